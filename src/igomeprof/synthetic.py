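"""Seeded simulators with planted ground truth for every pipeline stage.

Two generators: a phage-display selection simulator (mixture of planted PWM
motifs, amplification-skewed clone multiplicities, NNK reverse translation
and per-base sequencing errors) and a reactivity-matrix simulator (per-sample
serum reactivities with planted discriminative features, batch offsets and
duplicate spots). Both are pure functions of (config, seed), so any result
derived from them can be checked against the planted truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._alphabet import AA, N_AA, decode_peptides, nnk_codons, nnk_frequencies
from .reactivity import ReactivityMatrix, SpotTable, write_genepix
from .sequence_io import CopyTable

__all__ = [
    "SelectionConfig",
    "SelectionTruth",
    "simulate_selection",
    "selection_to_fastq",
    "ReactivityConfig",
    "ReactivityTruth",
    "simulate_reactivity",
    "reactivity_to_gpr",
    "DEFAULT_FLANK_LEFT",
    "DEFAULT_FLANK_RIGHT",
]

# vector flanks used by the simulated amplicons (arbitrary but fixed, chosen
# not to occur by chance inside a 21-nt insert at any realistic rate)
DEFAULT_FLANK_LEFT = "TCTCACTCT"
DEFAULT_FLANK_RIGHT = "GGTGGAGGT"


@dataclass
class SelectionConfig:
    """Planted mixture-of-motifs selection.

    ``K`` motif clusters of 7-mers, ``peptides_per_cluster`` clones each, a
    ``background_fraction`` of clones drawn from the unselected background,
    log-normal clone multiplicities (heavy-tailed phage amplification) and a
    per-base substitution ``error_rate`` at sequencing.
    """

    K: int = 3
    peptides_per_cluster: int = 200
    background_fraction: float = 0.1
    length: int = 7
    informative_positions: tuple[int, int] = (2, 4)
    motif_weight: float = 0.9
    mu_log_mult: float = 1.2
    sigma_log_mult: float = 0.7
    error_rate: float = 0.001
    flank_left: str = DEFAULT_FLANK_LEFT
    flank_right: str = DEFAULT_FLANK_RIGHT

    def __post_init__(self):
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if not 0.0 <= self.background_fraction <= 1.0:
            raise ValueError("background_fraction must be in [0, 1]")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must be in [0, 1)")


@dataclass
class SelectionTruth:
    """Ground truth emitted alongside simulated selections."""

    pwms: list[np.ndarray]
    peptides: list[str]
    labels: np.ndarray  # cluster id per clone, -1 for background clones
    multiplicities: np.ndarray
    error_rate: float


def _plant_pwms(cfg: SelectionConfig, rng: np.random.Generator) -> list[np.ndarray]:
    """Draw K cluster PWMs: background columns except 2-4 information-rich
    positions where most mass sits on one or two cluster-specific residues."""
    bg = nnk_frequencies()
    pwms = []
    # disjoint residue pools keep the planted motifs distinguishable (two
    # clusters sharing their favored residues would genuinely merge)
    pools = np.array_split(rng.permutation(N_AA), cfg.K)
    for k in range(cfg.K):
        pwm = np.tile(bg, (cfg.length, 1))
        lo, hi = cfg.informative_positions
        n_info = rng.integers(lo, hi + 1)
        positions = rng.choice(cfg.length, size=n_info, replace=False)
        for pos in positions:
            picks = rng.choice(pools[k], size=rng.integers(1, 3), replace=False)
            col = bg * (1.0 - cfg.motif_weight)
            col[picks] += cfg.motif_weight / len(picks)
            pwm[pos] = col / col.sum()
        pwms.append(pwm)
    return pwms


def _sample_from_pwm(pwm: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    L = pwm.shape[0]
    out = np.empty((n, L), dtype=np.int8)
    for pos in range(L):
        out[:, pos] = rng.choice(N_AA, size=n, p=pwm[pos])
    return out


def simulate_selection(
    config: SelectionConfig | None = None, seed: int = 0
) -> tuple[CopyTable, SelectionTruth]:
    """Simulate a panning selection as a clone table with multiplicities.

    Returns a :class:`CopyTable` over the emitted clones (multiplicities
    summed for coinciding sequences) and the planted truth. Sequencing errors
    apply at the read level only, so use :func:`selection_to_fastq` to obtain
    error-bearing reads.
    """
    cfg = config or SelectionConfig()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    pwms = _plant_pwms(cfg, rng)
    members, labels = [], []
    for k, pwm in enumerate(pwms):
        arr = _sample_from_pwm(pwm, cfg.peptides_per_cluster, rng)
        members.append(arr)
        labels.extend([k] * arr.shape[0])
    n_bg = int(round(cfg.background_fraction * cfg.K * cfg.peptides_per_cluster))
    if n_bg:
        bg_pwm = np.tile(nnk_frequencies(), (cfg.length, 1))
        members.append(_sample_from_pwm(bg_pwm, n_bg, rng))
        labels.extend([-1] * n_bg)
    arr = np.vstack(members)
    labels = np.asarray(labels)
    mult = np.maximum(
        1, np.round(rng.lognormal(cfg.mu_log_mult, cfg.sigma_log_mult, arr.shape[0]))
    ).astype(int)
    peptides = decode_peptides(arr)
    counts: dict[str, int] = {}
    for pep, m in zip(peptides, mult):
        counts[pep] = counts.get(pep, 0) + int(m)
    table = CopyTable(counts=counts, total_reads=int(mult.sum()))
    truth = SelectionTruth(
        pwms=pwms,
        peptides=peptides,
        labels=labels,
        multiplicities=mult,
        error_rate=cfg.error_rate,
    )
    return table, truth


def selection_to_fastq(
    truth: SelectionTruth,
    config: SelectionConfig,
    path,
    seed: int = 0,
) -> int:
    """Write simulated amplicon reads as FASTQ; returns the read count.

    Each clone is reverse-translated through uniformly chosen NNK codons,
    framed by the configured vector flanks, repeated ``multiplicity`` times
    and subjected to per-base substitution errors. Deterministic per seed
    (byte-identical files for identical inputs).
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xF0)))
    codons = nnk_codons()
    bases = np.array(list("ACGT"))
    n_reads = 0
    with open(path, "w") as fh:
        for clone_i, (pep, mult) in enumerate(
            zip(truth.peptides, truth.multiplicities)
        ):
            insert = "".join(
                codons[aa][rng.integers(0, len(codons[aa]))] for aa in pep
            )
            read = config.flank_left + insert + config.flank_right
            for copy_i in range(mult):
                arr = np.array(list(read))
                if config.error_rate > 0:
                    hit = rng.random(arr.shape[0]) < config.error_rate
                    for j in np.flatnonzero(hit):
                        choices = [b for b in "ACGT" if b != arr[j]]
                        arr[j] = choices[rng.integers(0, 3)]
                out = "".join(arr)
                fh.write(f"@clone{clone_i}_copy{copy_i}\n{out}\n+\n{'I' * len(out)}\n")
                n_reads += 1
    return n_reads


@dataclass
class ReactivityConfig:
    """Planted serum-reactivity cohort.

    Per-peptide baseline reactivities, iid Gaussian noise of scale ``sigma``,
    a shift of ``effect_size`` on ``n_discriminative`` features in the
    ``target`` diagnosis, additive per-batch offsets and (when emitted as GPR
    files) duplicate spots with multiplicative noise of CV ``duplicate_cv``.
    """

    panel: list[str] | int = 200
    groups: dict[str, int] = field(default_factory=lambda: {"GBM": 8, "C": 8})
    target: str = "GBM"
    n_discriminative: int = 10
    effect_size: float = 1.5
    batch_offsets: dict[str, float] = field(default_factory=lambda: {"G": 0.0})
    sigma: float = 0.5
    baseline_mean: float = 8.0
    baseline_sd: float = 1.0
    duplicate_cv: float = 0.1
    # fraction of target-group samples in which each discriminative feature
    # is actually elevated: below 1.0 the signature is a mosaic (no single
    # reactivity separates the group; only the combined profile does), which
    # is how polyspecific serum repertoires behave
    effect_coverage: float = 1.0
    # private reactivities: each peptide reacts strongly with this many
    # randomly chosen individual samples, emulating the individual variation
    # of serum repertoires (most peptides end up significantly reactive in
    # at least one patient)
    spikes_per_feature: int = 0
    spike_size: float = 4.0

    def __post_init__(self):
        if any(n < 2 for n in self.groups.values()):
            raise ValueError("every group needs >= 2 samples")
        if self.target not in self.groups:
            raise ValueError(f"target {self.target!r} not among groups")


@dataclass
class ReactivityTruth:
    discriminative: list[str]
    effect_size: float
    batch_offsets: dict[str, float]
    sigma: float


def simulate_reactivity(
    config: ReactivityConfig | None = None, seed: int = 0
) -> tuple[ReactivityMatrix, ReactivityTruth]:
    """Simulate a peptide x sample reactivity matrix with planted effects.

    Samples cycle through the configured batches within each diagnosis group;
    discriminative features are shifted by ``effect_size`` in the target
    group. Returns the matrix (with sample metadata) and the truth object.
    """
    cfg = config or ReactivityConfig()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    if isinstance(cfg.panel, int):
        panel = [f"pep{i:04d}" for i in range(cfg.panel)]
    else:
        panel = list(cfg.panel)
    n_disc = cfg.n_discriminative
    if n_disc > len(panel):
        raise ValueError("more discriminative features than panel peptides")
    disc_idx = rng.choice(len(panel), size=n_disc, replace=False)
    discriminative = [panel[i] for i in sorted(disc_idx)]
    batches = list(cfg.batch_offsets)
    samples, diags, sample_batches = [], [], []
    for diag, n in sorted(cfg.groups.items()):
        for i in range(n):
            samples.append(f"{diag}_{i:02d}")
            diags.append(diag)
            sample_batches.append(batches[i % len(batches)])
    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, len(panel))
    X = baseline[:, None] + rng.normal(0.0, cfg.sigma, (len(panel), len(samples)))
    disc_sorted = np.asarray(sorted(disc_idx), dtype=int)
    for j, (diag, b) in enumerate(zip(diags, sample_batches)):
        if diag == cfg.target and n_disc:
            covered = rng.random(n_disc) < cfg.effect_coverage
            X[disc_sorted[covered], j] += cfg.effect_size
        X[:, j] += cfg.batch_offsets[b]
    if cfg.spikes_per_feature:
        for i in range(len(panel)):
            hit = rng.choice(len(samples), size=cfg.spikes_per_feature, replace=False)
            X[i, hit] += cfg.spike_size
    values = pd.DataFrame(X, index=panel, columns=samples)
    meta = pd.DataFrame(
        {"diagnosis": diags, "batch": sample_batches}, index=samples
    )
    truth = ReactivityTruth(
        discriminative=discriminative,
        effect_size=cfg.effect_size,
        batch_offsets=dict(cfg.batch_offsets),
        sigma=cfg.sigma,
    )
    return ReactivityMatrix(values, meta), truth


def reactivity_to_gpr(
    matrix: ReactivityMatrix,
    outdir,
    duplicate_cv: float = 0.1,
    n_blocks: int = 2,
    seed: int = 0,
) -> list[Path]:
    """Emit one GPR file per sample with randomly placed duplicate spots.

    Log2 values become foreground intensities (background 50 added back);
    each peptide appears once in each of ``n_blocks`` blocks, in a per-block
    random row/column position, with multiplicative noise of CV
    ``duplicate_cv`` between the duplicates.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xA7)))
    paths = []
    peptides = list(matrix.values.index)
    n = len(peptides)
    ncol = int(np.ceil(np.sqrt(n)))
    for sample in matrix.values.columns:
        rows = []
        for block in range(1, n_blocks + 1):
            order = rng.permutation(n)
            for slot, i in enumerate(order):
                signal = 2.0 ** matrix.values.iloc[i][sample]
                noisy = signal * rng.normal(1.0, duplicate_cv)
                fg = max(noisy, 1.0) + 50.0
                rows.append(
                    {
                        "Block": block,
                        "Row": slot // ncol + 1,
                        "Column": slot % ncol + 1,
                        "ID": peptides[i],
                        "Name": peptides[i],
                        "F635 Median": round(fg, 1),
                        "B635 Median": 50.0,
                        "Flags": 0,
                    }
                )
        table = SpotTable(
            data=pd.DataFrame(rows),
            header={"Type": "GenePix Results 3", "Wavelengths": "635"},
        )
        path = outdir / f"{sample}.gpr"
        write_genepix(table, path)
        paths.append(path)
    return paths
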