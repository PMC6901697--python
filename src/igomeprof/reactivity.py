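"""Peptide-microarray reactivity pipeline.

From GenePix results tables (GPR) per serum sample to a batch-adjusted
peptide x sample reactivity matrix: background subtraction and log2, local
(per-block) median centering, duplicate-spot merging with CV quality control,
between-array quantile normalization, empirical-Bayes batch adjustment
(ComBat) and per-patient reactivity calls against the pooled remaining
patients.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

__all__ = [
    "SpotTable",
    "ReactivityMatrix",
    "read_genepix",
    "write_genepix",
    "preprocess_array",
    "normalize_set",
    "quantile_normalize",
    "combat_adjust",
    "call_reactivities",
    "balance_batches",
]

GPR_REQUIRED = ["Block", "Row", "Column", "ID", "F635 Median", "B635 Median", "Flags"]


@dataclass
class SpotTable:
    """Typed spot-level data of one scanned array."""

    data: pd.DataFrame
    header: dict = field(default_factory=dict)

    def __post_init__(self):
        missing = [c for c in GPR_REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"missing mandatory GPR columns: {missing}")
        coords = self.data[["Block", "Row", "Column"]]
        if coords.duplicated().any():
            raise ValueError("duplicate spot coordinates")
        if (self.data[["F635 Median", "B635 Median"]].to_numpy() < 0).any():
            raise ValueError("negative intensities")


def read_genepix(path) -> SpotTable:
    """Parse a GenePix results (GPR/ATF) file.

    The ATF header ('ATF 1.0', counts line, quoted key=value records) is
    preserved in ``SpotTable.header``; spot flags are kept as-is.
    """
    path = Path(path)
    with open(path) as fh:
        magic = fh.readline().split()
        if not magic or magic[0] != "ATF":
            raise ValueError(f"{path}: missing ATF header")
        counts = fh.readline().split()
        n_optional = int(counts[0])
        header = {}
        for _ in range(n_optional):
            line = fh.readline().strip().strip('"')
            if "=" in line:
                k, v = line.split("=", 1)
                header[k] = v
        data = pd.read_csv(fh, sep="\t")
    data.columns = [c.strip().strip('"') for c in data.columns]
    for col in ("Block", "Row", "Column", "Flags"):
        if col in data.columns:
            data[col] = data[col].astype(int)
    return SpotTable(data=data, header=header)


def write_genepix(table: SpotTable, path) -> None:
    """Write a SpotTable back to the GPR/ATF dialect read by read_genepix."""
    with open(path, "w") as fh:
        fh.write("ATF\t1.0\n")
        fh.write(f"{len(table.header)}\t{table.data.shape[1]}\n")
        for k, v in table.header.items():
            fh.write(f'"{k}={v}"\n')
        table.data.to_csv(fh, sep="\t", index=False)


@dataclass
class PreprocessReport:
    n_spots: int
    n_flagged: int
    flagged_peptides: list
    imputed_peptides: list


def preprocess_array(
    spots: SpotTable,
    cv_threshold: float = 0.5,
    local_centering: bool = True,
) -> tuple[pd.Series, PreprocessReport]:
    """Spot-level cleaning of one array to per-peptide log2 values.

    Flagged spots (negative GenePix flag) are dropped; the signal is
    ``log2(max(foreground - background, 1))``; blocks are median-centered to
    the array median (the local normalization step, removing print-tip /
    regional offsets); duplicate spots of one peptide are merged by mean, with
    peptides whose duplicate CV (on the linear scale) exceeds ``cv_threshold``
    flagged. Peptides with no unflagged spot are imputed as the array median
    and reported.
    """
    df = spots.data.copy()
    n_spots = len(df)
    flagged = df["Flags"] < 0
    df = df[~flagged]
    net = (df["F635 Median"] - df["B635 Median"]).clip(lower=1.0)
    df = df.assign(net=net, signal=np.log2(net))
    if local_centering and df["Block"].nunique() > 1:
        grand = df["signal"].median()
        df["signal"] = df["signal"] - df.groupby("Block")["signal"].transform("median") + grand
    grouped = df.groupby("ID")
    values = grouped["signal"].mean()
    cv = grouped["net"].std(ddof=1) / grouped["net"].mean()
    flagged_peptides = sorted(cv.index[cv.fillna(0.0) > cv_threshold])
    all_peptides = sorted(spots.data["ID"].unique())
    missing = [p for p in all_peptides if p not in values.index]
    if missing:
        log.warning("imputing %d peptide(s) with no unflagged spots", len(missing))
        values = pd.concat(
            [values, pd.Series(values.median(), index=missing)]
        )
    values = values.loc[all_peptides]
    report = PreprocessReport(
        n_spots=n_spots,
        n_flagged=int(flagged.sum()),
        flagged_peptides=flagged_peptides,
        imputed_peptides=missing,
    )
    return values, report


@dataclass
class ReactivityMatrix:
    """Normalized log2 reactivities with sample and peptide annotations.

    ``values`` is a peptides x samples DataFrame; ``sample_meta`` is indexed
    by sample with at least ``diagnosis`` and ``batch`` columns;
    ``peptide_meta`` optionally labels peptides with their library.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame | None = None
    peptide_meta: pd.DataFrame | None = None

    def __post_init__(self):
        if self.values.isna().any().any():
            raise ValueError("reactivity matrix contains missing values")
        if self.sample_meta is not None:
            missing = set(self.values.columns) - set(self.sample_meta.index)
            if missing:
                raise ValueError(f"samples without metadata: {sorted(missing)}")

    def subset_samples(self, samples) -> "ReactivityMatrix":
        meta = self.sample_meta.loc[samples] if self.sample_meta is not None else None
        return ReactivityMatrix(self.values[list(samples)], meta, self.peptide_meta)

    def to_dir(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.values.to_csv(outdir / "values.csv")
        if self.sample_meta is not None:
            self.sample_meta.to_csv(outdir / "samples.csv")
        if self.peptide_meta is not None:
            self.peptide_meta.to_csv(outdir / "peptides.csv")

    @classmethod
    def from_dir(cls, outdir) -> "ReactivityMatrix":
        outdir = Path(outdir)
        values = pd.read_csv(outdir / "values.csv", index_col=0)
        sm = pp = None
        if (outdir / "samples.csv").exists():
            sm = pd.read_csv(outdir / "samples.csv", index_col=0)
        if (outdir / "peptides.csv").exists():
            pp = pd.read_csv(outdir / "peptides.csv", index_col=0)
        return cls(values, sm, pp)


def quantile_normalize(values: pd.DataFrame) -> pd.DataFrame:
    """Force every column to the mean empirical distribution (rank-assigned)."""
    arr = values.to_numpy(dtype=float)
    order = np.argsort(arr, axis=0, kind="stable")
    mean_sorted = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        out[order[:, j], j] = mean_sorted
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def normalize_set(
    arrays: dict[str, pd.Series],
    sample_meta: pd.DataFrame | None = None,
    peptide_meta: pd.DataFrame | None = None,
) -> ReactivityMatrix:
    """Assemble per-array values into a quantile-normalized matrix.

    All arrays must share the same peptide panel. A single array passes
    through unchanged (there is nothing to equalize between arrays).
    """
    names = list(arrays)
    panels = [tuple(arrays[n].index) for n in names]
    ref = set(panels[0])
    for n, p in zip(names, panels):
        if set(p) != ref:
            raise ValueError(f"array {n!r} has a different peptide panel")
    values = pd.DataFrame({n: arrays[n] for n in names})
    if len(names) > 1:
        values = quantile_normalize(values)
    return ReactivityMatrix(values, sample_meta, peptide_meta)


def _design_matrix(labels: pd.Series) -> np.ndarray:
    cats = pd.Categorical(labels)
    return pd.get_dummies(cats, drop_first=True).to_numpy(dtype=float)


def combat_adjust(
    matrix: ReactivityMatrix | pd.DataFrame,
    batch_col: str = "batch",
    preserve_col: str | None = None,
    batches: pd.Series | None = None,
    eb_iters: int = 100,
    tol: float = 1e-6,
) -> ReactivityMatrix | pd.DataFrame:
    """Parametric empirical-Bayes location/scale batch adjustment (ComBat).

    Per feature, the model is x = alpha + X beta + gamma_batch +
    delta_batch * eps. Features are standardized, batch means/variances are
    shrunk toward their across-feature priors by an iterative EB solve, and
    the data are restored without the batch terms. ``preserve_col`` adds a
    biological covariate (e.g. diagnosis) to the standardization model so its
    effect is not absorbed into batch means. Deterministic. A single batch is
    returned unchanged with a warning.
    """
    if isinstance(matrix, ReactivityMatrix):
        values = matrix.values
        if batches is None:
            batches = matrix.sample_meta[batch_col]
        preserve = (
            matrix.sample_meta[preserve_col] if preserve_col is not None else None
        )
    else:
        values = matrix
        if batches is None:
            raise ValueError("batches required for a bare DataFrame")
        preserve = None
    batches = batches.loc[values.columns]
    levels = sorted(batches.unique())
    if len(levels) < 2:
        log.warning("single batch: ComBat adjustment is the identity")
        return matrix
    counts = batches.value_counts()
    if (counts < 2).any():
        raise ValueError("every batch needs >= 2 samples")
    if preserve is not None:
        cross = pd.crosstab(batches, preserve)
        if (cross.astype(bool).sum(axis=0) < 2).any():
            log.warning("a preserved group occurs in a single batch (confounding)")

    X = values.to_numpy(dtype=float)  # features x samples
    n = X.shape[1]
    batch_dummies = pd.get_dummies(pd.Categorical(batches, categories=levels)).to_numpy(
        dtype=float
    )
    design = batch_dummies
    if preserve is not None:
        design = np.hstack([design, _design_matrix(preserve)])
    # per-feature OLS of x on [batch dummies | covariates]
    beta_hat = np.linalg.lstsq(design, X.T, rcond=None)[0]  # (q, features)
    n_batches = batch_dummies.shape[1]
    batch_sizes = batch_dummies.sum(axis=0)
    grand_mean = (batch_sizes / n) @ beta_hat[:n_batches]  # per-feature alpha
    fitted = design @ beta_hat
    var_pooled = ((X.T - fitted) ** 2).mean(axis=0)
    var_pooled = np.where(var_pooled < 1e-12, 1e-12, var_pooled)
    stand_mean = np.tile(grand_mean, (n, 1))
    if preserve is not None:
        stand_mean = stand_mean + design[:, n_batches:] @ beta_hat[n_batches:]
    Z = (X.T - stand_mean) / np.sqrt(var_pooled)  # samples x features

    adjusted = Z.copy()
    for b in range(n_batches):
        idx = batch_dummies[:, b] == 1
        nb = int(batch_sizes[b])
        Zb = Z[idx]
        gamma_hat = Zb.mean(axis=0)
        delta_hat = Zb.var(axis=0, ddof=1)
        gamma_bar, tau2 = gamma_hat.mean(), gamma_hat.var(ddof=1)
        m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
        aprior = (2 * s2 + m**2) / s2
        bprior = (m * s2 + m**3) / s2
        gamma_star, delta_star = gamma_hat.copy(), delta_hat.copy()
        for _ in range(eb_iters):
            g_new = (nb * tau2 * gamma_hat + delta_star * gamma_bar) / (
                nb * tau2 + delta_star
            )
            sum2 = ((Zb - g_new) ** 2).sum(axis=0)
            d_new = (0.5 * sum2 + bprior) / (nb / 2.0 + aprior - 1.0)
            change = max(
                np.abs(g_new - gamma_star).max(), np.abs(d_new - delta_star).max()
            )
            gamma_star, delta_star = g_new, d_new
            if change < tol:
                break
        adjusted[idx] = (Zb - gamma_star) / np.sqrt(delta_star)

    out = (adjusted * np.sqrt(var_pooled) + stand_mean).T
    out_df = pd.DataFrame(out, index=values.index, columns=values.columns)
    if isinstance(matrix, ReactivityMatrix):
        return ReactivityMatrix(out_df, matrix.sample_meta, matrix.peptide_meta)
    return out_df


@dataclass
class ReactivityCalls:
    """Per peptide x sample significance of reactivity vs the pooled rest."""

    z: pd.DataFrame
    p: pd.DataFrame
    significant: pd.DataFrame
    q_level: float

    def counts_per_sample(self) -> pd.Series:
        return self.significant.sum(axis=0)

    def features_significant_anywhere(self) -> list:
        return list(self.significant.index[self.significant.any(axis=1)])


def call_reactivities(
    matrix: ReactivityMatrix | pd.DataFrame, q: float = 0.05
) -> ReactivityCalls:
    """Call each sample's significant reactivities against the pooled rest.

    For every peptide and sample, z = (x - mean_rest) / sd_rest over the other
    samples, a two-sided normal p-value, and Benjamini-Hochberg FDR control
    within each sample at level ``q``. Peptides with zero rest-variance are
    marked non-significant.
    """
    values = matrix.values if isinstance(matrix, ReactivityMatrix) else matrix
    if values.shape[1] < 3:
        raise ValueError("need >= 3 samples")
    X = values.to_numpy(dtype=float)
    n = X.shape[1]
    total = X.sum(axis=1, keepdims=True)
    mean_rest = (total - X) / (n - 1)
    ss_total = (X**2).sum(axis=1, keepdims=True)
    var_rest = (ss_total - X**2) / (n - 1) - mean_rest**2
    var_rest = var_rest * (n - 1) / (n - 2)  # unbiased over the n-1 rest samples
    sd_rest = np.sqrt(np.clip(var_rest, 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (X - mean_rest) / sd_rest
    degenerate = ~np.isfinite(z)
    if degenerate.any():
        log.warning("%d cells with zero rest-variance marked non-significant", degenerate.sum())
    z = np.where(degenerate, 0.0, z)
    p = 2.0 * stats.norm.sf(np.abs(z))
    sig = np.zeros_like(p, dtype=bool)
    for j in range(n):
        sig[:, j] = multipletests(p[:, j], alpha=q, method="fdr_bh")[0]
    sig[degenerate] = False
    idx, cols = values.index, values.columns
    return ReactivityCalls(
        z=pd.DataFrame(z, idx, cols),
        p=pd.DataFrame(p, idx, cols),
        significant=pd.DataFrame(sig, idx, cols),
        q_level=q,
    )


def balance_batches(
    sample_meta: pd.DataFrame,
    caps: dict[tuple[str, str], int] | None = None,
    exclude_groups: list[str] | None = None,
    group_col: str = "diagnosis",
    batch_col: str = "batch",
) -> pd.DataFrame:
    """Subset samples to balance group sizes across batches before ComBat.

    ``caps`` limits the number of samples kept per (group, batch) cell (the
    first rows in metadata order are kept); ``exclude_groups`` drops whole
    diagnostic groups. Returns the retained metadata; dropped samples remain
    available as a held-out testing set.
    """
    meta = sample_meta.copy()
    if exclude_groups:
        meta = meta[~meta[group_col].isin(exclude_groups)]
    if caps:
        keep = []
        for _, row in meta.reset_index().iterrows():
            key = (row[group_col], row[batch_col])
            cap = caps.get(key)
            if cap is None:
                keep.append(row.iloc[0])
            else:
                already = sum(
                    1
                    for s in keep
                    if sample_meta.loc[s, group_col] == key[0]
                    and sample_meta.loc[s, batch_col] == key[1]
                )
                if already < cap:
                    keep.append(row.iloc[0])
        meta = meta.loc[keep]
    return meta
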