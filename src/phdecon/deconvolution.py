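"""Linear deconvolution of four-condition expression data into LPS, pH and
interaction components.

Each gene's log2 fold changes across five pairwise condition comparisons are
modelled as ``Y = X @ beta + eps`` where ``beta = (LPS, pH, INT)``.  Components
are tested against a shifted null (|effect| <= ``beta0_fold``) with a central
t-distribution at ``df = 5 * n_replicate_sets - 3``, and genes are classified
into regulatory-logic groups and merged pH-sensitivity categories.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

#: The four culture conditions, in canonical column order.
CONDITIONS = ("pH74", "pH74_LPS", "pH65", "pH65_LPS")

#: Names of the three deconvolved components.
COMPONENTS = ("LPS", "pH", "INT")

#: The five contrasts: (numerator condition, denominator condition,
#: loading vector over (LPS, pH, INT)).
CONTRASTS = (
    ("pH74_LPS", "pH74", (1, 0, 0)),
    ("pH65", "pH74", (0, 1, 0)),
    ("pH65_LPS", "pH65", (1, 0, 1)),
    ("pH65_LPS", "pH74_LPS", (0, 1, 1)),
    ("pH65_LPS", "pH74", (1, 1, 1)),
)

#: Pairwise comparisons used by the differential-expression prefilter
#: (numerator, denominator).
PREFILTER_COMPARISONS = (
    ("pH74_LPS", "pH74"),
    ("pH65", "pH74"),
    ("pH65_LPS", "pH65"),
    ("pH65_LPS", "pH74_LPS"),
)

NORM_TOTAL = 1e7

CATEGORIES = (
    "pH_insensitive",
    "pH_antagonistic",
    "pH_synergistic",
    "pH_only",
    "other",
    "unassigned",
)


class ValidationError(ValueError):
    """Raised when an input table violates the expected structure."""


# ---------------------------------------------------------------------------
# Data containers
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Gene x sample count table with condition/replicate annotations.

    Parameters
    ----------
    counts:
        DataFrame of non-negative counts, genes as rows, sample ids as columns.
    design:
        DataFrame with columns ``sample_id``, ``condition`` and
        ``replicate_set``; every replicate set must contain each of the four
        conditions exactly once.
    """

    counts: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        required = {"sample_id", "condition", "replicate_set"}
        if not required.issubset(self.design.columns):
            raise ValidationError(
                f"design table must have columns {sorted(required)}"
            )
        if self.design["sample_id"].duplicated().any():
            dup = self.design.loc[self.design["sample_id"].duplicated(), "sample_id"]
            raise ValidationError(f"duplicate sample ids in design: {list(dup)}")
        missing = set(self.design["sample_id"]) - set(self.counts.columns)
        if missing:
            raise ValidationError(f"samples missing from counts table: {sorted(missing)}")
        bad = set(self.design["condition"]) - set(CONDITIONS)
        if bad:
            raise ValidationError(f"unknown conditions in design: {sorted(bad)}")
        for rep, sub in self.design.groupby("replicate_set"):
            conds = sorted(sub["condition"])
            if conds != sorted(CONDITIONS):
                missing_c = sorted(set(CONDITIONS) - set(conds))
                extra = sorted(c for c in conds if conds.count(c) > 1)
                detail = f"missing {missing_c}" if missing_c else f"duplicated {extra}"
                raise ValidationError(
                    f"replicate set {rep!r} is invalid: {detail}"
                )
        vals = self.counts[list(self.design["sample_id"])].to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise ValidationError("counts table contains non-numeric cells")
        if (vals < 0).any():
            raise ValidationError("counts must be non-negative")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def replicate_sets(self) -> list:
        return sorted(self.design["replicate_set"].unique())

    def n_replicate_sets(self) -> int:
        return self.design["replicate_set"].nunique()

    def condition_array(self) -> np.ndarray:
        """Counts as an array of shape (n_genes, n_replicate_sets, 4).

        The last axis follows :data:`CONDITIONS` order; replicate sets are in
        sorted order.
        """
        reps = self.replicate_sets
        out = np.empty((len(self.counts), len(reps), 4))
        lut = {
            (row.replicate_set, row.condition): row.sample_id
            for row in self.design.itertuples()
        }
        for i, rep in enumerate(reps):
            for j, cond in enumerate(CONDITIONS):
                out[:, i, j] = self.counts[lut[(rep, cond)]].to_numpy()
        return out


@dataclass
class ComponentEstimate:
    """Per-gene OLS fit of the deconvolution model."""

    gene_id: str
    y: np.ndarray
    beta: np.ndarray  # (LPS, pH, INT) in log2-fold units
    se: np.ndarray
    sigma2: float
    r2: float
    df: int
    t: np.ndarray | None = None
    p: np.ndarray | None = None


@dataclass
class GeneClassification:
    gene_id: str
    sig_flags: tuple
    sign_pattern: tuple  # each in {"+", "-", "0"}
    group_id: object  # 1..20 or "unassigned"
    category: str


# ---------------------------------------------------------------------------
# Pipeline stages
# ---------------------------------------------------------------------------


def normalize_matrix(matrix: ExpressionMatrix, total: float = NORM_TOTAL) -> ExpressionMatrix:
    """Rescale every sample column so it sums to ``total`` (default 1e7)."""
    cols = list(matrix.design["sample_id"])
    sums = matrix.counts[cols].sum(axis=0)
    zero = sums[sums == 0]
    if len(zero):
        raise ValidationError(f"all-zero sample(s): {list(zero.index)}")
    scaled = matrix.counts.copy()
    scaled[cols] = matrix.counts[cols] * (total / sums)
    return ExpressionMatrix(scaled, matrix.design.copy())


def build_design_matrix(n_replicate_sets: int) -> np.ndarray:
    """Stack the five contrast loading vectors once per replicate set.

    Returns a ``(5 * n_replicate_sets, 3)`` binary array of column rank 3.
    """
    if n_replicate_sets < 1:
        raise ValueError("n_replicate_sets must be >= 1")
    block = np.array([load for _, _, load in CONTRASTS], dtype=float)
    return np.vstack([block] * n_replicate_sets)


def compute_fold_changes(
    condition_counts: np.ndarray, pseudocount: float = 2.0
) -> np.ndarray:
    """Log2 fold changes for the five contrasts in every replicate set.

    Parameters
    ----------
    condition_counts:
        Array of shape ``(n_replicate_sets, 4)`` in :data:`CONDITIONS` order,
        or ``(4,)`` for a single replicate set.
    pseudocount:
        Added to numerator and denominator before the ratio.

    Returns the response vector ``Y`` of length ``5 * n_replicate_sets``
    (contrast blocks of replicate set 1 first, then set 2, ...).
    """
    arr = np.atleast_2d(np.asarray(condition_counts, dtype=float))
    if arr.shape[1] != 4:
        raise ValueError("expected one count per condition (4 columns)")
    idx = {c: i for i, c in enumerate(CONDITIONS)}
    out = np.empty(arr.shape[0] * 5)
    for r in range(arr.shape[0]):
        for k, (num, den, _) in enumerate(CONTRASTS):
            out[5 * r + k] = np.log2(
                (arr[r, idx[num]] + pseudocount) / (arr[r, idx[den]] + pseudocount)
            )
    return out


def fit_gene(y: np.ndarray, X: np.ndarray, gene_id: str = "") -> ComponentEstimate:
    """Exact ordinary-least-squares fit of ``y = X @ beta + eps``.

    ``sigma2`` is RSS / df with ``df = len(y) - 3``; standard errors come from
    the diagonal of ``sigma2 * (X'X)^-1``; ``r2`` is centered (TSS about the
    mean of y, defined as 0 when y is constant).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if y.shape[0] != X.shape[0]:
        raise ValueError("length of y must equal rows of X")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ y
    resid = y - X @ beta
    rss = float(resid @ resid)
    df = y.shape[0] - X.shape[1]
    sigma2 = rss / df if df > 0 else np.nan
    se = np.sqrt(sigma2 * np.diag(xtx_inv))
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    return ComponentEstimate(
        gene_id=gene_id, y=y, beta=beta, se=se, sigma2=sigma2, r2=r2, df=df
    )


def _fit_many(Y: np.ndarray, X: np.ndarray):
    """Vectorized OLS over genes. ``Y`` has shape (n_genes, n_rows)."""
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = Y @ X @ xtx_inv.T  # (n_genes, 3)
    resid = Y - beta @ X.T
    rss = np.einsum("ij,ij->i", resid, resid)
    df = X.shape[0] - X.shape[1]
    sigma2 = rss / df
    se = np.sqrt(sigma2[:, None] * np.diag(xtx_inv)[None, :])
    tss = np.sum((Y - Y.mean(axis=1, keepdims=True)) ** 2, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(tss > 0, 1.0 - rss / np.where(tss > 0, tss, 1.0), 0.0)
    return beta, se, sigma2, r2, df


def test_component(
    estimate: ComponentEstimate, beta0_fold: float = 1.5
) -> tuple[np.ndarray, np.ndarray]:
    """One-sided t-test of each component against a shifted null.

    The null states the true effect is within ``beta0_fold`` in the direction
    of the estimate: for ``beta_j >= 0`` the statistic is
    ``(beta_j - log2(beta0_fold)) / se_j`` tested in the upper tail, for
    negative estimates ``(beta_j + log2(beta0_fold)) / se_j`` in the lower
    tail.  Updates ``estimate.t``/``estimate.p`` in place and returns them.
    """
    if estimate.df < 1:
        raise ValueError("df must be >= 1")
    if beta0_fold <= 1:
        raise ValueError("beta0_fold must be > 1")
    t, p = _test_components_arr(
        estimate.beta[None, :], estimate.se[None, :], estimate.df, beta0_fold
    )
    estimate.t, estimate.p = t[0], p[0]
    return estimate.t, estimate.p


def _test_components_arr(beta, se, df, beta0_fold):
    b0 = np.log2(beta0_fold)
    pos = beta >= 0
    shifted = np.where(pos, beta - b0, beta + b0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = shifted / se
    # se == 0 conventions: outside the null -> p = 0, inside -> p = 1
    t = np.where(
        (se == 0) & (np.abs(beta) > b0),
        np.where(shifted > 0, np.inf, -np.inf),
        t,
    )
    t = np.where((se == 0) & (np.abs(beta) <= b0), 0.0, t)
    p = np.where(pos, stats.t.sf(t, df), stats.t.cdf(t, df))
    p = np.where((se == 0) & (np.abs(beta) > b0), 0.0, p)
    p = np.where((se == 0) & (np.abs(beta) <= b0), 1.0, p)
    return t, p


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------


def load_group_table() -> pd.DataFrame:
    """The package's canonical enumeration of (significance, sign) patterns.

    Columns: ``group_id`` (1..20) and the sign of each component in
    {``+``, ``-``, ``0``} (``0`` meaning not significant).
    """
    ref = importlib.resources.files("phdecon").joinpath("data/group_table.tsv")
    with ref.open("r") as fh:
        return pd.read_csv(fh, sep="\t", dtype={"group_id": int}, keep_default_na=False)


_GROUP_LUT: dict | None = None


def _group_lookup() -> Mapping[tuple, int]:
    global _GROUP_LUT
    if _GROUP_LUT is None:
        tbl = load_group_table()
        _GROUP_LUT = {
            (row.LPS, row.pH, row.INT): row.group_id for row in tbl.itertuples()
        }
    return _GROUP_LUT


def classify_gene(
    estimate: ComponentEstimate,
    beta_min_fold: float = 2.0,
    p_max: float = 0.05,
    r2_min: float = 0.8,
) -> GeneClassification:
    """Assign significance flags, sign pattern, group id and merged category.

    A component is significant iff ``|beta| >= log2(beta_min_fold)``, its
    shifted-null p-value is below ``p_max`` and the gene-level fit has
    ``r2 > r2_min``.
    """
    if estimate.p is None:
        test_component(estimate)
    b_min = np.log2(beta_min_fold)
    sig = tuple(
        bool(abs(b) >= b_min and p < p_max and estimate.r2 > r2_min)
        for b, p in zip(estimate.beta, estimate.p)
    )
    signs = tuple(
        ("+" if b > 0 else "-") if s else "0" for b, s in zip(estimate.beta, sig)
    )
    group_id = _group_lookup().get(signs, "unassigned") if any(sig) else "unassigned"
    sig_lps, sig_ph, sig_int = sig
    if not any(sig):
        category = "unassigned"
    elif sig_lps and not sig_int:
        category = "pH_insensitive"
    elif sig_lps and sig_int:
        category = (
            "pH_synergistic" if signs[0] == signs[2] else "pH_antagonistic"
        )
    elif sig_ph and not sig_lps and not sig_int:
        category = "pH_only"
    else:
        category = "other"
    return GeneClassification(
        gene_id=estimate.gene_id,
        sig_flags=sig,
        sign_pattern=signs,
        group_id=group_id,
        category=category,
    )


# ---------------------------------------------------------------------------
# Prefilter
# ---------------------------------------------------------------------------


def _welch_p(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Vectorized two-sided Welch test per gene; zero-variance pairs are
    resolved by comparing means (0 if different, 1 if equal)."""
    na, nb = a.shape[1], b.shape[1]
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va = a.var(axis=1, ddof=1)
    vb = b.var(axis=1, ddof=1)
    denom2 = va / na + vb / nb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / np.sqrt(denom2)
        df = denom2**2 / (
            (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
        )
    p = np.where(
        denom2 > 0,
        2 * stats.t.sf(np.abs(t), np.where(denom2 > 0, df, 1.0)),
        np.where(ma == mb, 1.0, 0.0),
    )
    return p


def prefilter_de_genes(
    matrix: ExpressionMatrix,
    fc_threshold: float = 3.0,
    q_threshold: float = 0.05,
    min_mean: float = 5.0,
    pseudocount: float = 2.0,
) -> pd.Index:
    """Retain genes differentially expressed in any pairwise comparison.

    A gene passes when, for at least one of the four pairwise comparisons,
    the pseudocounted fold change exceeds ``fc_threshold`` (in either
    direction), the BH-adjusted Welch p-value across replicate sets is below
    ``q_threshold``, and the gene's mean normalized expression exceeds
    ``min_mean``.  With a single replicate set the adjusted-p criterion is
    disabled (warning logged).
    """
    arr = matrix.condition_array()  # (genes, reps, 4)
    n_reps = arr.shape[1]
    idx = {c: i for i, c in enumerate(CONDITIONS)}
    mean_ok = arr.mean(axis=(1, 2)) > min_mean
    log_counts = np.log2(arr + pseudocount)
    use_p = n_reps >= 2
    if not use_p:
        logger.warning(
            "prefilter: only one replicate set; adjusted-p criterion disabled"
        )
    keep = np.zeros(arr.shape[0], dtype=bool)
    for num, den in PREFILTER_COMPARISONS:
        mnum = arr[:, :, idx[num]].mean(axis=1)
        mden = arr[:, :, idx[den]].mean(axis=1)
        fc = (mnum + pseudocount) / (mden + pseudocount)
        fc_ok = np.maximum(fc, 1.0 / fc) > fc_threshold
        if use_p:
            p = _welch_p(log_counts[:, :, idx[num]], log_counts[:, :, idx[den]])
            q = multipletests(p, method="fdr_bh")[1]
            p_ok = q < q_threshold
        else:
            p_ok = np.ones_like(fc_ok)
        keep |= fc_ok & p_ok & mean_ok
    return matrix.gene_ids[keep]


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------


@dataclass
class DeconvolutionConfig:
    pseudocount: float = 2.0
    beta0_fold: float = 1.5
    beta_min_fold: float = 2.0
    p_max: float = 0.05
    r2_min: float = 0.8
    r2_report: float = 0.9
    normalize: bool = True
    prefilter: bool = True
    fc_threshold: float = 3.0
    q_threshold: float = 0.05
    min_mean: float = 5.0


RESULT_COLUMNS = [
    "gene_id",
    "beta_LPS", "beta_pH", "beta_INT",
    "se_LPS", "se_pH", "se_INT",
    "t_LPS", "t_pH", "t_INT",
    "p_LPS", "p_pH", "p_INT",
    "sigma2", "r2", "group_id", "category",
]


def run_deconvolution(
    matrix: ExpressionMatrix, config: DeconvolutionConfig | None = None
) -> tuple[pd.DataFrame, dict]:
    """Full per-gene pipeline: normalize, prefilter, fit, test, classify.

    Returns the result table (one row per retained gene, input gene order)
    and a summary dict with per-category counts and filter funnel sizes.
    """
    cfg = config or DeconvolutionConfig()
    if cfg.normalize:
        matrix = normalize_matrix(matrix)
    n_total = len(matrix.counts)
    if cfg.prefilter:
        kept = prefilter_de_genes(
            matrix, cfg.fc_threshold, cfg.q_threshold, cfg.min_mean, cfg.pseudocount
        )
        sub = ExpressionMatrix(matrix.counts.loc[kept], matrix.design.copy())
    else:
        sub = matrix
    R = sub.n_replicate_sets()
    X = build_design_matrix(R)
    arr = sub.condition_array()
    n_genes = arr.shape[0]
    if n_genes == 0:
        empty = pd.DataFrame(columns=RESULT_COLUMNS)
        summary = {
            "n_genes_input": n_total,
            "n_genes_prefiltered": 0,
            "category_counts": {c: 0 for c in CATEGORIES},
            "frac_r2_above_report": None,
            "config": vars(cfg),
        }
        return empty, summary
    Y = np.stack([compute_fold_changes(arr[g], cfg.pseudocount) for g in range(n_genes)])
    beta, se, sigma2, r2, df = _fit_many(Y, X)
    t, p = _test_components_arr(beta, se, df, cfg.beta0_fold)

    rows = []
    cats = dict.fromkeys(CATEGORIES, 0)
    for g, gid in enumerate(sub.gene_ids):
        est = ComponentEstimate(
            gene_id=str(gid), y=Y[g], beta=beta[g], se=se[g],
            sigma2=float(sigma2[g]), r2=float(r2[g]), df=df, t=t[g], p=p[g],
        )
        cls = classify_gene(est, cfg.beta_min_fold, cfg.p_max, cfg.r2_min)
        cats[cls.category] += 1
        rows.append(
            [str(gid), *beta[g], *se[g], *t[g], *p[g],
             float(sigma2[g]), float(r2[g]), cls.group_id, cls.category]
        )
    result = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    summary = {
        "n_genes_input": n_total,
        "n_genes_prefiltered": n_genes,
        "df": int(df),
        "category_counts": cats,
        "frac_r2_above_report": float(np.mean(r2 > cfg.r2_report)),
        "config": vars(cfg),
    }
    for cat, n in cats.items():
        logger.info("deconvolution: %s = %d genes", cat, n)
    return result, summary
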