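"""Pipeline orchestration: staged runs from a single YAML/dict config.

Stages run in dependency order (simulate_selection -> extract -> cluster ->
design); each consumes the previous stage's artifacts from the run directory
and an explicit per-stage seed derived from the run seed. A machine-readable
manifest records parameters, seeds and output checksums, so reruns with the
same config are byte-verifiable.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml

from . import gibbs, library_design, sequence_io, synthetic
from .composition import estimate_background

__all__ = ["run_pipeline", "load_config", "STAGES"]

STAGES = ("simulate_selection", "extract", "cluster", "design")

_ALLOWED_KEYS = {
    "seed": int,
    "outdir": str,
    "stages": list,
    "simulate_selection": dict,
    "extract": dict,
    "cluster": dict,
    "design": dict,
}


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _validate(config: dict) -> None:
    unknown = set(config) - set(_ALLOWED_KEYS)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for k, v in config.items():
        if not isinstance(v, _ALLOWED_KEYS[k]):
            raise ValueError(f"config key {k!r} must be {_ALLOWED_KEYS[k].__name__}")
    stages = config.get("stages", list(STAGES))
    bad = [s for s in stages if s not in STAGES]
    if bad:
        raise ValueError(f"unknown stages: {bad}")
    order = [STAGES.index(s) for s in stages]
    if order != sorted(order):
        raise ValueError("stages must be in dependency order")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_seed(seed: int, stage: str) -> int:
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"stage {stage!r}: missing upstream artifact {path.name}"
        )
    return path


def run_pipeline(config: dict | str | Path) -> Path:
    """Execute the configured stages; returns the artifact directory.

    The config is schema-checked before any stage runs. Every stochastic
    stage consumes a seed derived from the run seed and recorded in
    ``manifest.json`` together with per-file SHA-256 checksums.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    _validate(config)
    seed = config.get("seed", 0)
    outdir = Path(config.get("outdir", "igomeprof_run"))
    outdir.mkdir(parents=True, exist_ok=True)
    stages = config.get("stages", list(STAGES))
    manifest = {"seed": seed, "stages": []}

    for stage in stages:
        params = dict(config.get(stage, {}))
        stage_seed = _stage_seed(seed, stage)
        outputs: list[Path] = []
        if stage == "simulate_selection":
            cfg = synthetic.SelectionConfig(**params)
            table, truth = synthetic.simulate_selection(cfg, seed=stage_seed)
            fq = outdir / "reads.fastq"
            synthetic.selection_to_fastq(truth, cfg, fq, seed=stage_seed)
            labels_path = outdir / "selection_truth.json"
            labels_path.write_text(
                json.dumps(
                    {
                        "peptides": truth.peptides,
                        "labels": truth.labels.tolist(),
                        "multiplicities": truth.multiplicities.tolist(),
                    }
                )
            )
            outputs = [fq, labels_path]
        elif stage == "extract":
            fq = _require(outdir / "reads.fastq", stage)
            locator = sequence_io.InsertLocator(
                flank_left=params.pop("flank_left", synthetic.DEFAULT_FLANK_LEFT),
                flank_right=params.pop("flank_right", synthetic.DEFAULT_FLANK_RIGHT),
            )
            low = params.pop("min_copies", 2)
            high = params.pop("max_copies", 11)
            records = sequence_io.read_sequence_records(fq, "fastq")
            peptides, report = sequence_io.extract_insert_peptides(records, locator)
            table = sequence_io.tally_copies(peptides)
            kept, _ = sequence_io.filter_copy_window(table, low, high)
            tsv = outdir / "peptides.tsv"
            sequence_io.CopyTable(
                {p: table.counts[p] for p in kept}, table.total_reads
            ).to_tsv(tsv)
            drops = outdir / "drop_report.json"
            report.to_json(drops)
            outputs = [tsv, drops]
        elif stage == "cluster":
            tsv = _require(outdir / "peptides.tsv", stage)
            table = sequence_io.CopyTable.from_tsv(tsv)
            grid = params.pop("grid", [2, 3, 4])
            gp = gibbs.GibbsParams(**params)
            scan = gibbs.scan_cluster_number(
                sorted(table.counts), grid, params=gp, seed=stage_seed
            )
            model = outdir / "cluster_model.json"
            scan["states"][scan["best_G"]].to_json(model)
            curve = outdir / "kld_curve.tsv"
            with open(curve, "w") as fh:
                fh.write("G\tkld\n")
                for G in grid:
                    fh.write(f"{G}\t{scan['curve'][G]:.6f}\n")
            outputs = [model, curve]
        elif stage == "design":
            model = _require(outdir / "cluster_model.json", stage)
            state = gibbs.ClusteringState.from_json(model)
            bg = estimate_background("nnk")
            signif = library_design.cluster_significance(
                state, bg, M=params.pop("M", 10_000), seed=stage_seed,
                alpha=params.pop("alpha", library_design.SIGNIFICANCE_ALPHA),
            )
            k_top = params.pop("k_top", None)
            n_sig = sum(r.significant for r in signif)
            if n_sig == 0:
                raise RuntimeError("stage 'design': no significant clusters")
            k_top = min(k_top or n_sig, n_sig)
            sym = library_design.design_sym(state, signif, k_top=k_top)
            sym_path = outdir / "sym.tsv"
            sym.to_tsv(sym_path)
            outputs = [sym_path]
        manifest["stages"].append(
            {
                "name": stage,
                "seed": stage_seed,
                "params": {k: v for k, v in config.get(stage, {}).items()},
                "outputs": {p.name: _sha256(p) for p in outputs},
            }
        )

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir
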