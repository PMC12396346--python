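"""Single-cell expression filtering, normalization, signature scoring, and the
stemness/lineage two-dimensional cell-state representation.

The processing chain is:

    filter_cells -> filter_genes -> normalize_log -> center_within_sample
        -> signature_score / state_scores -> stemness_lineage -> highlight_cells

plus pseudo-bulk aggregation and within-/across-sample correlation screening
with Benjamini-Hochberg FDR control.

Expression values are normalized as ``log2(CPM/10 + 1)`` (the divisor of 10
reflects an assumed per-cell complexity of ~100k rather than 1M molecules).
Scoring and centering are performed per sample.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ExpressionMatrix",
    "filter_cells",
    "filter_genes",
    "normalize_log",
    "center_within_sample",
    "signature_score",
    "state_scores",
    "stemness_lineage",
    "highlight_cells",
    "pseudo_bulk",
    "correlate_within_samples",
    "correlate_across_samples",
    "fdr_adjust",
]

VALID_UNITS = ("counts", "cpm", "tpm", "lognorm")
VALID_PLATFORMS = ("smartseq2", "umi")

#: per-million values are divided by this before the log2(x+1) transform
LOG_DIVISOR = 10.0

STATE_KEYS = ("OPC", "OC", "AC")


@dataclass
class ExpressionMatrix:
    """A gene x cell expression matrix with per-cell annotations.

    Parameters
    ----------
    values
        2-D float array, genes in rows, cells in columns.
    gene_ids, cell_ids
        Unique string identifiers for rows / columns.
    sample_of_cell
        Sample label per cell.
    platform_of_sample
        Mapping from every sample label to ``"smartseq2"`` or ``"umi"``.
    malignant
        Boolean flag per cell.
    unit
        One of ``counts``, ``cpm``, ``tpm``, ``lognorm``.
    centered
        True once per-sample gene centering has been applied (values may
        then be negative).
    """

    values: np.ndarray
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    sample_of_cell: np.ndarray
    platform_of_sample: dict
    malignant: np.ndarray
    unit: str = "counts"
    centered: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.sample_of_cell = np.asarray(self.sample_of_cell, dtype=object)
        self.malignant = np.asarray(self.malignant, dtype=bool)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D genes x cells array")
        ng, nc = self.values.shape
        if len(self.gene_ids) != ng:
            raise ValueError(f"gene_ids length {len(self.gene_ids)} != {ng} rows")
        if len(self.cell_ids) != nc:
            raise ValueError(f"cell_ids length {len(self.cell_ids)} != {nc} columns")
        if len(self.sample_of_cell) != nc or len(self.malignant) != nc:
            raise ValueError("per-cell annotations must match the number of cells")
        if len(set(self.gene_ids)) != ng:
            raise ValueError("gene_ids must be unique")
        if len(set(self.cell_ids)) != nc:
            raise ValueError("cell_ids must be unique")
        if self.unit not in VALID_UNITS:
            raise ValueError(f"unit must be one of {VALID_UNITS}, got {self.unit!r}")
        if not self.centered and self.values.size and self.values.min() < 0:
            raise ValueError("expression values must be non-negative")
        missing = sorted(set(self.sample_of_cell) - set(self.platform_of_sample))
        if missing:
            raise ValueError(f"samples without a platform: {missing}")
        bad = {s: p for s, p in self.platform_of_sample.items() if p not in VALID_PLATFORMS}
        if bad:
            raise ValueError(f"unknown platforms {bad}; expected one of {VALID_PLATFORMS}")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    @property
    def samples(self) -> list:
        """Sample labels in order of first appearance."""
        return list(pd.unique(self.sample_of_cell))

    def detected_genes_per_cell(self) -> np.ndarray:
        return (self.values > 0).sum(axis=0)

    def subset_cells(self, idx) -> "ExpressionMatrix":
        idx = np.asarray(idx)
        return replace(
            self,
            values=self.values[:, idx],
            cell_ids=self.cell_ids[idx],
            sample_of_cell=self.sample_of_cell[idx],
            malignant=self.malignant[idx],
        )

    def subset_genes(self, idx) -> "ExpressionMatrix":
        idx = np.asarray(idx)
        return replace(self, values=self.values[idx, :], gene_ids=self.gene_ids[idx])

    def gene_index(self, gene: str) -> int:
        hits = np.flatnonzero(self.gene_ids == gene)
        if hits.size == 0:
            raise KeyError(f"gene {gene!r} not in matrix")
        return int(hits[0])


def _require_prelog(m: ExpressionMatrix, op: str) -> None:
    if m.unit == "lognorm":
        raise ValueError(f"{op} requires pre-log values (counts/cpm/tpm), got lognorm")


def filter_cells(
    m: ExpressionMatrix,
    smartseq2_cutoff: int = 2000,
    default_cutoff: int = 1000,
) -> ExpressionMatrix:
    """Drop cells with too few detected genes (entries > 0).

    Cutoffs are inclusive minima: 2000 detected genes for smart-seq2
    samples, 1000 for any other platform. Cell order is preserved.
    """
    _require_prelog(m, "filter_cells")
    detected = m.detected_genes_per_cell()
    cutoffs = np.array(
        [
            smartseq2_cutoff
            if m.platform_of_sample[s] == "smartseq2"
            else default_cutoff
            for s in m.sample_of_cell
        ]
    )
    keep = np.flatnonzero(detected >= cutoffs)
    if keep.size == 0:
        raise ValueError("all cells filtered: no cell passes the detected-gene cutoff")
    return m.subset_cells(keep)


def filter_genes(m: ExpressionMatrix, k: int = 7000) -> ExpressionMatrix:
    """Keep the ``k`` genes with the highest mean expression across cells.

    Ties are broken by lexicographic gene id; row order of the survivors is
    preserved. If the matrix has fewer than ``k`` genes it is returned as is.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if m.n_genes <= k:
        return m
    means = m.values.mean(axis=1)
    # sort by (-mean, gene_id); lexsort uses the last key as primary
    order = np.lexsort((m.gene_ids.astype(str), -means))
    keep = np.sort(order[:k])
    return m.subset_genes(keep)


def normalize_log(m: ExpressionMatrix) -> ExpressionMatrix:
    """Normalize to ``log2(CPM/10 + 1)``.

    Counts are first scaled per cell to sum to 1e6 (CPM); CPM/TPM inputs are
    transformed directly. The unit tag becomes ``lognorm``.
    """
    _require_prelog(m, "normalize_log")
    v = m.values
    if m.unit == "counts":
        totals = v.sum(axis=0)
        zero = np.flatnonzero(totals == 0)
        if zero.size:
            raise ValueError(
                f"cells with zero total counts cannot be CPM-normalized: "
                f"{list(m.cell_ids[zero[:5]])}"
            )
        v = v / totals * 1e6
    out = np.log2(v / LOG_DIVISOR + 1.0)
    return replace(m, values=out, unit="lognorm")


def center_within_sample(m: ExpressionMatrix) -> ExpressionMatrix:
    """Subtract each gene's mean across the cells of each sample."""
    if m.unit != "lognorm":
        raise ValueError("center_within_sample requires lognorm values")
    out = m.values.copy()
    for s in m.samples:
        cols = np.flatnonzero(m.sample_of_cell == s)
        if cols.size == 1:
            warnings.warn(f"sample {s!r} has a single cell; it centers to zero")
        out[:, cols] -= out[:, cols].mean(axis=1, keepdims=True)
    return replace(m, values=out, centered=True)


def _bin_genes(means: np.ndarray, gene_ids: np.ndarray, n_bins: int) -> np.ndarray:
    """Assign each gene to an expression bin (0..n_bins-1) by mean rank."""
    order = np.lexsort((gene_ids.astype(str), means))
    bin_of = np.empty(len(means), dtype=int)
    for b, chunk in enumerate(np.array_split(order, n_bins)):
        bin_of[chunk] = b
    return bin_of


def signature_score(
    m: ExpressionMatrix,
    genes,
    n_bins: int = 30,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.Series:
    """Score cells for a gene signature against expression-matched controls.

    The score is the per-cell mean of centered expression over the signature
    genes minus the mean over a control set: genes are binned into ``n_bins``
    by mean expression and, for each signature gene, ``n_ctrl`` control genes
    are drawn (seeded; without replacement within the bin where possible)
    from that gene's bin. ``n_ctrl=0`` disables the control subtraction.

    The matrix must be ``lognorm``; centering (subtraction of each gene's
    mean over the cells provided) is applied internally, so passing one
    sample at a time yields per-sample scoring.
    """
    if m.unit != "lognorm":
        raise ValueError("signature_score requires lognorm values")
    genes = list(dict.fromkeys(genes))
    present = {g: i for i, g in enumerate(m.gene_ids)}
    sig_idx = [present[g] for g in genes if g in present]
    missing = [g for g in genes if g not in present]
    if not sig_idx:
        raise ValueError(f"no signature gene found in matrix; missing: {missing}")
    if missing:
        warnings.warn(f"{len(missing)} signature genes absent from matrix: {missing[:5]}")

    means = m.values.mean(axis=1)
    centered = m.values - means[:, None]
    score = centered[sig_idx].mean(axis=0)

    if n_ctrl > 0:
        n_bins_eff = min(n_bins, m.n_genes)
        bin_of = _bin_genes(means, m.gene_ids, n_bins_eff)
        members = {b: np.flatnonzero(bin_of == b) for b in range(n_bins_eff)}
        sig_set = set(sig_idx)
        rng = np.random.default_rng(seed)
        ctrl: list = []
        for gi in sig_idx:
            pool = np.array([j for j in members[bin_of[gi]] if j not in sig_set])
            if pool.size == 0:
                pool = np.array([j for j in members[bin_of[gi]] if j != gi])
            if pool.size == 0:
                continue
            take = rng.choice(pool, size=n_ctrl, replace=pool.size < n_ctrl)
            ctrl.extend(take.tolist())
        if ctrl:
            score = score - centered[ctrl].mean(axis=0)

    return pd.Series(score, index=m.cell_ids, name="score")


def _sig_seed(seed: int, name: str) -> list:
    # stable per-signature stream, independent of sample identity so that
    # duplicated samples receive identical control draws
    return [int(seed), zlib.crc32(name.encode())]


def state_scores(
    m: ExpressionMatrix,
    signatures: dict,
    n_bins: int = 30,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-cell OPC/OC/AC signature scores, computed one sample at a time.

    ``signatures`` must contain the keys OPC, OC and AC. Returns a frame
    indexed by cell id with columns ``sample``, ``opc_score``, ``oc_score``,
    ``ac_score``, in the matrix's cell order.
    """
    missing = [k for k in STATE_KEYS if k not in signatures]
    if missing:
        raise ValueError(f"signature set lacks required keys: {missing}")
    if m.unit != "lognorm":
        raise ValueError("state_scores requires lognorm values")

    cols = {f"{k.lower()}_score": np.empty(m.n_cells) for k in STATE_KEYS}
    for s in m.samples:
        cells = np.flatnonzero(m.sample_of_cell == s)
        sub = m.subset_cells(cells)
        for k in STATE_KEYS:
            sc = signature_score(
                sub, signatures[k], n_bins=n_bins, n_ctrl=n_ctrl,
                seed=_sig_seed(seed, k),
            )
            cols[f"{k.lower()}_score"][cells] = sc.to_numpy()
    out = pd.DataFrame(cols, index=m.cell_ids)
    out.insert(0, "sample", m.sample_of_cell)
    out.index.name = "cell_id"
    return out


def stemness_lineage(
    table: pd.DataFrame, jitter_eps: float = 0.05, seed: int = 0
) -> pd.DataFrame:
    """Add stemness and lineage coordinates to a state-score table.

    stemness = opc_score - max(oc_score, ac_score).
    lineage  = max(oc_score, ac_score), multiplied by -1 iff the AC score is
    strictly the higher of the two; when both OC and AC scores are negative
    the lineage is replaced by a seeded Uniform(-jitter_eps, +jitter_eps)
    draw and the ``jittered`` flag is set.
    """
    for c in ("opc_score", "oc_score", "ac_score"):
        if c not in table.columns:
            raise ValueError(f"state-score table lacks column {c!r}")
    opc = table["opc_score"].to_numpy(float)
    oc = table["oc_score"].to_numpy(float)
    ac = table["ac_score"].to_numpy(float)
    dominant = np.maximum(oc, ac)
    stemness = opc - dominant
    sign = np.where(ac > oc, -1.0, 1.0)  # tie resolved as OC (positive)
    lineage = sign * dominant
    jittered = (oc < 0) & (ac < 0)
    rng = np.random.default_rng(seed)
    u = rng.uniform(-jitter_eps, jitter_eps, size=len(table))
    lineage = np.where(jittered, u, lineage)
    out = table.copy()
    out["stemness"] = stemness
    out["lineage"] = lineage
    out["jittered"] = jittered
    return out


def highlight_cells(
    m: ExpressionMatrix, gene: str, threshold: float = 1.0
) -> pd.Series:
    """Flag cells whose centered expression of ``gene`` exceeds ``threshold``
    (strict inequality). Requires a per-sample-centered matrix."""
    if not m.centered:
        raise ValueError("highlight_cells requires a per-sample centered matrix")
    row = m.values[m.gene_index(gene)]
    return pd.Series(row > threshold, index=m.cell_ids, name=f"{gene}_high")


def pseudo_bulk(m: ExpressionMatrix) -> pd.DataFrame:
    """Sample x gene pseudo-bulk: per-sample mean over malignant cells,
    then ``log2(v/10 + 1)``. No centering is applied.

    Counts are converted to per-cell CPM before averaging. Samples without
    malignant cells are dropped with a warning.
    """
    _require_prelog(m, "pseudo_bulk")
    if not m.malignant.any():
        raise ValueError("no malignant cells in the matrix")
    v = m.values
    if m.unit == "counts":
        totals = v.sum(axis=0)
        zero = np.flatnonzero(totals == 0)
        if zero.size:
            raise ValueError(
                f"cells with zero total counts: {list(m.cell_ids[zero[:5]])}"
            )
        v = v / totals * 1e6
    rows = {}
    for s in m.samples:
        cols = np.flatnonzero((m.sample_of_cell == s) & m.malignant)
        if cols.size == 0:
            warnings.warn(f"sample {s!r} has no malignant cells; dropped")
            continue
        rows[s] = np.log2(v[:, cols].mean(axis=1) / LOG_DIVISOR + 1.0)
    out = pd.DataFrame.from_dict(rows, orient="index", columns=m.gene_ids)
    out.index.name = "sample"
    return out


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xd = x - x.mean()
    yd = y - y.mean()
    denom = np.sqrt((xd * xd).sum() * (yd * yd).sum())
    return float((xd * yd).sum() / denom)


def _corr(x: np.ndarray, y: np.ndarray, method: str) -> float:
    if method == "pearson":
        return _pearson(x, y)
    if method == "spearman":
        return float(stats.spearmanr(x, y).statistic)
    raise ValueError(f"unknown correlation method {method!r}")


def correlate_within_samples(
    m: ExpressionMatrix,
    scores: pd.Series,
    genes,
    min_cells: int = 3,
    method: str = "pearson",
) -> pd.DataFrame:
    """Within-sample correlation between a per-cell score and each gene.

    For every sample with at least ``min_cells`` cells, correlates the gene's
    expression values with the score across that sample's cells; samples with
    zero variance in either variable are skipped with a warning. Reports, per
    gene, the mean correlation across samples, the number of contributing
    samples, and a two-sided one-sample t-test p-value of the per-sample
    correlations against zero (NaN when fewer than two samples contribute).
    """
    score_vec = scores.reindex(m.cell_ids).to_numpy(float)
    if np.isnan(score_vec).any():
        raise ValueError("scores missing for some cells in the matrix")
    records = []
    for g in genes:
        row = m.values[m.gene_index(g)]
        rs = []
        for s in m.samples:
            cols = np.flatnonzero(m.sample_of_cell == s)
            if cols.size < min_cells:
                continue
            x, y = row[cols], score_vec[cols]
            if x.std() == 0 or y.std() == 0:
                warnings.warn(f"sample {s!r} skipped for gene {g!r}: zero variance")
                continue
            rs.append(_corr(x, y, method))
        if rs:
            mean_r = float(np.mean(rs))
            p = float(stats.ttest_1samp(rs, 0.0).pvalue) if len(rs) >= 2 else np.nan
        else:
            warnings.warn(f"gene {g!r}: every sample skipped; correlation missing")
            mean_r, p = np.nan, np.nan
        records.append(
            {"gene": g, "mean_r": mean_r, "n_units": len(rs), "p_value": p}
        )
    return pd.DataFrame(records).set_index("gene")


def correlate_across_samples(
    pb: pd.DataFrame,
    sample_scores: pd.Series,
    study_of_sample: pd.Series,
    genes=None,
    min_samples: int = 3,
    method: str = "pearson",
) -> pd.DataFrame:
    """Across-sample pseudo-bulk correlation per study, averaged over studies.

    ``pb`` is a sample x gene frame (see :func:`pseudo_bulk`); scores and
    study labels are indexed by sample. Studies with fewer than
    ``min_samples`` samples are skipped with a warning. The p-value is a
    one-sample t-test of the per-study correlations against zero, or the
    Pearson test p-value when a single study contributes.
    """
    genes = list(pb.columns) if genes is None else list(genes)
    scores = sample_scores.reindex(pb.index).to_numpy(float)
    studies = study_of_sample.reindex(pb.index)
    records = []
    for g in genes:
        if g not in pb.columns:
            raise KeyError(f"gene {g!r} not in pseudo-bulk matrix")
        col = pb[g].to_numpy(float)
        rs = []
        single_p = np.nan
        for st in pd.unique(studies):
            rowsel = (studies == st).to_numpy()
            if rowsel.sum() < min_samples:
                warnings.warn(f"study {st!r} skipped: fewer than {min_samples} samples")
                continue
            x, y = col[rowsel], scores[rowsel]
            if x.std() == 0 or y.std() == 0:
                warnings.warn(f"study {st!r} skipped for gene {g!r}: zero variance")
                continue
            rs.append(_corr(x, y, method))
            if method == "pearson":
                single_p = float(stats.pearsonr(x, y).pvalue)
        if rs:
            mean_r = float(np.mean(rs))
            p = float(stats.ttest_1samp(rs, 0.0).pvalue) if len(rs) >= 2 else single_p
        else:
            mean_r, p = np.nan, np.nan
        records.append(
            {"gene": g, "mean_r": mean_r, "n_units": len(rs), "p_value": p}
        )
    return pd.DataFrame(records).set_index("gene")


def fdr_adjust(p_values, alpha: float = 0.05):
    """Benjamini-Hochberg step-up adjustment.

    Returns ``(q_values, significant)`` where ``significant = q < alpha``.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    flags = np.where(ok, q < alpha, False)
    return q, flags
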