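"""Untargeted-metabolomics statistics: preprocessing, PCA, OPLS-DA, screening.

The substrate is a samples x metabolites intensity matrix with a three-level
group factor (control / model / treatment).  The screening pipeline follows
common metabolomics practice:

1. log transform, column centering and unit-variance scaling;
2. PCA for cluster inspection;
3. OPLS-DA per two-group comparison — one predictive partial-least-squares
   component after removal of ``n_ortho`` components of class-orthogonal
   variation (orthogonal signal correction in the Trygg–Wold style).  The
   model reports R2Y (explained class variance in fit), Q2 (explained class
   variance under stratified k-fold cross-validation with the whole pipeline
   refit per fold) and per-metabolite VIP scores (variable importance in
   projection; mean squared VIP is identically 1);
4. differential metabolites: VIP > 1 and Welch t-test p < 0.05 (both strict);
5. three-group comparison: one-way ANOVA plus Dunn's rank-based post test
   with Benjamini–Hochberg correction over the three pairwise contrasts;
6. reversal biomarkers: metabolites differential in both model-vs-control and
   treatment-vs-model with opposite directions of change — the signature of a
   treatment that pushes a disease-altered metabolite back toward normal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA as _SKPCA
from sklearn.model_selection import StratifiedKFold

from .enrich import bh_adjust

__all__ = [
    "IntensityMatrix",
    "preprocess",
    "pca",
    "OPLSDA",
    "OPLSDAResults",
    "oplsda",
    "DifferentialResult",
    "screen_differential",
    "three_group_compare",
    "venn_differential",
    "ReversalBiomarker",
    "find_reversed",
]

GROUPS = ("control", "model", "treatment")


# ---------------------------------------------------------------------------
# Data container
# ---------------------------------------------------------------------------

@dataclass
class IntensityMatrix:
    """Samples x metabolites intensity matrix with per-sample group labels."""

    intensities: pd.DataFrame  # rows = samples, columns = metabolites
    groups: pd.Series  # aligned to intensities.index

    def __post_init__(self) -> None:
        self.groups = self.groups.reindex(self.intensities.index)
        if self.groups.isna().any():
            raise ValueError("every sample needs a group label")
        if (self.intensities.to_numpy() < 0).any():
            raise ValueError("intensities must be nonnegative")

    @property
    def metabolites(self) -> list[str]:
        return list(self.intensities.columns)

    def subset(self, groups: Sequence[str]) -> "IntensityMatrix":
        mask = self.groups.isin(list(groups))
        return IntensityMatrix(self.intensities.loc[mask].copy(), self.groups.loc[mask].copy())

    def to_tsv(self, path: str | Path) -> None:
        out = self.intensities.copy()
        out.insert(0, "group", self.groups)
        out.to_csv(path, sep="\t", index_label="sample")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "IntensityMatrix":
        df = pd.read_csv(path, sep="\t", index_col="sample")
        if "group" not in df.columns:
            raise ValueError("intensity table needs a 'group' column")
        groups = df.pop("group").astype(str)
        return cls(df.astype(float), groups)


def preprocess(
    matrix: IntensityMatrix | pd.DataFrame,
    log_transform: bool = True,
    scaling: str = "unit_variance",
) -> tuple[pd.DataFrame, dict]:
    """Log transform (optional), center, and scale an intensity matrix.

    Zeros are replaced column-wise by half the smallest positive value before
    the log.  Columns that are entirely zero, or that have zero variance when
    unit-variance scaling is requested, are dropped and named in the returned
    metadata.  Centering is always applied.
    """
    if scaling not in ("unit_variance", "pareto", "none"):
        raise ValueError(f"unknown scaling {scaling!r}")
    df = matrix.intensities if isinstance(matrix, IntensityMatrix) else matrix
    x = df.astype(float).copy()
    dropped = sorted(x.columns[(x == 0).all(axis=0)])
    x = x.drop(columns=dropped)
    if log_transform:
        for col in x.columns:
            vals = x[col]
            if (vals == 0).any():
                half_min = vals[vals > 0].min() / 2.0
                x[col] = vals.replace(0.0, half_min)
        x = np.log(x)
    x = x - x.mean(axis=0)
    if scaling in ("unit_variance", "pareto"):
        sd = x.std(axis=0, ddof=1)
        degenerate = sorted(sd.index[(sd == 0) | sd.isna()])
        if degenerate:
            if scaling == "unit_variance":
                warnings.warn(
                    f"dropping {len(degenerate)} zero-variance metabolites", stacklevel=2
                )
                dropped += degenerate
                x = x.drop(columns=degenerate)
                sd = sd.drop(index=degenerate)
            else:
                sd = sd.replace(0.0, 1.0)
        x = x / (sd if scaling == "unit_variance" else np.sqrt(sd))
    meta = {"dropped": dropped, "log_transform": log_transform, "scaling": scaling}
    return x, meta


def pca(matrix: pd.DataFrame, n_components: int):
    """PCA scores, orthonormal loadings and explained-variance fractions."""
    x = np.asarray(matrix, dtype=float)
    max_comp = min(x.shape[0] - 1, x.shape[1])
    if not 1 <= n_components <= max_comp:
        raise ValueError(f"n_components must be in [1, {max_comp}], got {n_components}")
    model = _SKPCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(x)
    return scores, model.components_.T, model.explained_variance_ratio_


# ---------------------------------------------------------------------------
# OPLS-DA model
# ---------------------------------------------------------------------------

def _osc_pls_fit(x: np.ndarray, y: np.ndarray, n_ortho: int):
    """Orthogonal signal correction followed by one predictive PLS component.

    Expects centered x and y.  Returns a dict of fitted vectors; the filtered
    matrix is deflated in place of a copy of x.
    """
    xf = x.copy()
    w_orthos, p_orthos, t_orthos = [], [], []
    for _ in range(n_ortho):
        w = xf.T @ y
        nw = np.linalg.norm(w)
        if nw == 0:
            break
        w /= nw
        t = xf @ w
        p = xf.T @ t / (t @ t)
        w_o = p - ((w @ p) / (w @ w)) * w
        n_o = np.linalg.norm(w_o)
        if n_o < 1e-12:  # no class-orthogonal variation left
            break
        w_o /= n_o
        t_o = xf @ w_o
        p_o = xf.T @ t_o / (t_o @ t_o)
        xf -= np.outer(t_o, p_o)
        w_orthos.append(w_o)
        p_orthos.append(p_o)
        t_orthos.append(t_o)
    w = xf.T @ y
    nw = np.linalg.norm(w)
    if nw == 0:
        raise ValueError("class vector has no covariance with the data")
    w /= nw
    t = xf @ w
    p = xf.T @ t / (t @ t)
    q = (y @ t) / (t @ t)
    return {
        "w": w,
        "t": t,
        "p": p,
        "q": q,
        "w_orthos": w_orthos,
        "p_orthos": p_orthos,
        "t_orthos": t_orthos,
    }


def _osc_pls_predict(fit: dict, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Apply the fitted orthogonal filter then the predictive component."""
    xf = x.copy()
    t_orthos = []
    for w_o, p_o in zip(fit["w_orthos"], fit["p_orthos"]):
        t_o = xf @ w_o
        xf -= np.outer(t_o, p_o)
        t_orthos.append(t_o)
    t = xf @ fit["w"]
    return t * fit["q"], t


class OPLSDA:
    """OPLS discriminant analysis of a two-group metabolite matrix.

    Parameters
    ----------
    x : array-like, samples x metabolites
        Preprocessed (centered/scaled) data matrix.
    labels : sequence
        Two-level group assignment per sample; the lexicographically first
        level is coded -1, the second +1.
    n_ortho : int
        Number of class-orthogonal components removed before the single
        predictive component (0 reduces the model to plain PLS1-DA).
    """

    def __init__(self, x, labels, n_ortho: int = 1):
        self.x = np.asarray(x, dtype=float)
        labels = np.asarray(list(labels))
        self.classes = sorted(pd.unique(labels).tolist(), key=str)
        if len(self.classes) != 2:
            raise ValueError(f"OPLS-DA needs exactly two groups, got {self.classes}")
        counts = [(labels == c).sum() for c in self.classes]
        if min(counts) == 0:
            raise ValueError("each group must be nonempty")
        self.labels = labels
        self.y = np.where(labels == self.classes[0], -1.0, 1.0)
        if n_ortho < 0:
            raise ValueError("n_ortho must be >= 0")
        self.n_ortho = n_ortho

    def fit(self, cv_folds: int = 7, seed: int = 0) -> "OPLSDAResults":
        x, y = self.x, self.y
        x_mean, y_mean = x.mean(axis=0), y.mean()
        xc, yc = x - x_mean, y - y_mean
        core = _osc_pls_fit(xc, yc, self.n_ortho)
        y_hat = core["t"] * core["q"] + y_mean
        ss_tot = float(((y - y_mean) ** 2).sum())
        r2y = 1.0 - float(((y - y_hat) ** 2).sum()) / ss_tot

        # Cross-validated Q2: refit centering + orthogonal filter + PLS per fold.
        min_class = min((self.labels == c).sum() for c in self.classes)
        folds = cv_folds
        if min_class < cv_folds:
            warnings.warn(
                f"reducing cv_folds from {cv_folds} to {min_class} "
                "(smallest group size)",
                stacklevel=2,
            )
            folds = int(min_class)
        press = 0.0
        if folds >= 2:
            skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
            for train, test in skf.split(x, self.labels):
                xm, ym = x[train].mean(axis=0), y[train].mean()
                fold_fit = _osc_pls_fit(x[train] - xm, y[train] - ym, self.n_ortho)
                pred, _ = _osc_pls_predict(fold_fit, x[test] - xm)
                press += float(((y[test] - (pred + ym)) ** 2).sum())
            q2 = 1.0 - press / ss_tot
        else:
            q2 = float("nan")

        p_m = x.shape[1]
        vip = np.sqrt(p_m) * np.abs(core["w"])  # single predictive component
        return OPLSDAResults(
            model=self,
            predictive_scores=core["t"],
            orthogonal_scores=np.column_stack(core["t_orthos"])
            if core["t_orthos"]
            else np.empty((x.shape[0], 0)),
            predictive_loadings=core["p"],
            orthogonal_loadings=np.column_stack(core["p_orthos"])
            if core["p_orthos"]
            else np.empty((p_m, 0)),
            weights=core["w"],
            r2y=r2y,
            q2=q2,
            vip=vip,
            n_ortho=len(core["t_orthos"]),
            cv_folds=folds,
            seed=seed,
            fitted_y=y_hat,
        )


@dataclass
class OPLSDAResults:
    """Fitted OPLS-DA estimates, cross-validation diagnostics and VIP scores."""

    model: OPLSDA
    predictive_scores: np.ndarray
    orthogonal_scores: np.ndarray
    predictive_loadings: np.ndarray
    orthogonal_loadings: np.ndarray
    weights: np.ndarray
    r2y: float
    q2: float
    vip: np.ndarray
    n_ortho: int
    cv_folds: int
    seed: int
    fitted_y: np.ndarray = field(repr=False, default=None)

    def permutation_test(self, n_permutations: int = 100, seed: int = 0) -> np.ndarray:
        """Q2 values under random label permutation (model-validity check)."""
        rng = np.random.default_rng(seed)
        q2s = np.empty(n_permutations)
        for i in range(n_permutations):
            perm = rng.permutation(self.model.labels)
            res = OPLSDA(self.model.x, perm, n_ortho=self.model.n_ortho).fit(
                cv_folds=self.cv_folds, seed=int(rng.integers(2**31 - 1))
            )
            q2s[i] = res.q2
        return q2s

    def summary(self) -> str:
        c0, c1 = self.model.classes
        lines = [
            "OPLS-DA Results",
            "=" * 46,
            f"groups:            {c0} (-1) vs {c1} (+1)",
            f"n samples:         {self.model.x.shape[0]}",
            f"n metabolites:     {self.model.x.shape[1]}",
            f"orthogonal comps:  {self.n_ortho}",
            f"R2Y:               {self.r2y:.4f}",
            f"Q2 ({self.cv_folds}-fold CV):    {self.q2:.4f}",
            f"VIP > 1:           {(self.vip > 1).sum()} metabolites",
            "=" * 46,
        ]
        return "\n".join(lines)


def oplsda(
    matrix: pd.DataFrame,
    labels: Sequence[str],
    n_ortho: int = 1,
    cv_folds: int = 7,
    seed: int = 0,
) -> OPLSDAResults:
    """Functional wrapper: fit :class:`OPLSDA` on a processed matrix."""
    return OPLSDA(matrix, labels, n_ortho=n_ortho).fit(cv_folds=cv_folds, seed=seed)


# ---------------------------------------------------------------------------
# Differential screening
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DifferentialResult:
    metabolite_id: str
    vip: float
    p: float
    direction: int  # sign of (group_b mean - group_a mean) on the processed scale
    significant: bool


def screen_differential(
    matrix: IntensityMatrix,
    group_a: str,
    group_b: str,
    vip_threshold: float = 1.0,
    p_threshold: float = 0.05,
    seed: int = 0,
    n_ortho: int = 1,
    cv_folds: int = 7,
    log_transform: bool = True,
    scaling: str = "unit_variance",
    equal_var: bool = False,
) -> list[DifferentialResult]:
    """Differential metabolites between two groups: VIP > 1 and t-test p < 0.05.

    VIP comes from an OPLS-DA fit of the two-group processed submatrix; the
    per-metabolite p-value is a two-sided Welch t-test (Student with
    ``equal_var=True``) on the processed scale.  Both thresholds are strict,
    so vip == 1.0 or p == 0.05 is not significant.  Metabolites dropped during
    preprocessing (constant columns) are reported with vip 0, p 1 and
    direction 0.
    """
    sub = matrix.subset([group_a, group_b])
    counts = sub.groups.value_counts()
    if counts.get(group_a, 0) < 3 or counts.get(group_b, 0) < 3:
        raise ValueError("each group needs at least 3 samples")
    processed, meta = preprocess(sub, log_transform=log_transform, scaling=scaling)
    res = oplsda(processed, sub.groups.tolist(), n_ortho=n_ortho, cv_folds=cv_folds, seed=seed)
    mask_a = (sub.groups == group_a).to_numpy()
    mask_b = (sub.groups == group_b).to_numpy()
    xa = processed.loc[mask_a]
    xb = processed.loc[mask_b]
    tt = stats.ttest_ind(xa, xb, axis=0, equal_var=equal_var)
    results = []
    vip_by_col = dict(zip(processed.columns, res.vip))
    p_by_col = dict(zip(processed.columns, np.asarray(tt.pvalue)))
    delta = (xb.mean(axis=0) - xa.mean(axis=0)).to_dict()
    for met in matrix.metabolites:
        if met in vip_by_col:
            v = float(vip_by_col[met])
            p = float(p_by_col[met])
            d = int(np.sign(delta[met]))
            sig = (v > vip_threshold) and (p < p_threshold)
        else:  # dropped as constant during preprocessing
            v, p, d, sig = 0.0, 1.0, 0, False
        results.append(DifferentialResult(met, v, p, d, sig))
    return results


def three_group_compare(matrix: IntensityMatrix, log_transform: bool = True) -> pd.DataFrame:
    """One-way ANOVA plus Dunn's post test (BH-adjusted) per metabolite.

    Dunn's test compares mean ranks over the pooled samples with the normal
    approximation and tie correction; BH adjustment is applied within each
    metabolite's three pairwise contrasts.  A metabolite constant across all
    samples is reported with p 1 and the ``degenerate`` flag set.
    """
    levels = sorted(matrix.groups.unique(), key=str)
    if len(levels) != 3:
        raise ValueError(f"expected three groups, got {levels}")
    counts = matrix.groups.value_counts()
    if (counts < 3).any():
        raise ValueError("each group needs at least 3 samples")
    x = matrix.intensities.astype(float).copy()
    if log_transform:
        for col in x.columns:
            vals = x[col]
            if (vals == 0).any():
                pos = vals[vals > 0]
                # an all-zero column stays constant and is flagged degenerate
                x[col] = vals.replace(0.0, pos.min() / 2.0 if len(pos) else 1.0)
        x = np.log(x)
    pairs = [(levels[0], levels[1]), (levels[0], levels[2]), (levels[1], levels[2])]
    rows = []
    masks = {g: (matrix.groups == g).to_numpy() for g in levels}
    for met in x.columns:
        vals = x[met].to_numpy()
        by_group = [vals[masks[g]] for g in levels]
        row: dict = {"metabolite_id": met}
        if np.ptp(vals) == 0:
            row["anova_p"] = 1.0
            row["degenerate"] = True
            for a, b in pairs:
                row[f"p_{a}_{b}"] = 1.0
            rows.append(row)
            continue
        row["degenerate"] = False
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            row["anova_p"] = float(stats.f_oneway(*by_group).pvalue)
        raw = _dunn_pairwise(vals, masks, pairs)
        adj = bh_adjust(raw)
        for (a, b), p in zip(pairs, adj):
            row[f"p_{a}_{b}"] = float(p)
        rows.append(row)
    return pd.DataFrame(rows).set_index("metabolite_id")


def _dunn_pairwise(values: np.ndarray, masks: dict, pairs: list[tuple[str, str]]) -> list[float]:
    """Two-sided Dunn z-test p-values for the requested group pairs."""
    n_total = len(values)
    ranks = stats.rankdata(values)
    # tie correction: sum(t^3 - t) / (12 (N - 1))
    _, tie_counts = np.unique(values, return_counts=True)
    tie_corr = float((tie_counts**3 - tie_counts).sum()) / (12.0 * (n_total - 1))
    var_term = n_total * (n_total + 1) / 12.0 - tie_corr
    mean_ranks = {g: ranks[m].mean() for g, m in masks.items()}
    sizes = {g: int(m.sum()) for g, m in masks.items()}
    out = []
    for a, b in pairs:
        se = np.sqrt(var_term * (1.0 / sizes[a] + 1.0 / sizes[b]))
        if se == 0:
            out.append(1.0)
            continue
        z = (mean_ranks[a] - mean_ranks[b]) / se
        out.append(min(1.0, float(2.0 * stats.norm.sf(abs(z)))))
    return out


def venn_differential(
    diff_mc: Sequence[DifferentialResult], diff_mt: Sequence[DifferentialResult]
) -> dict[str, int]:
    """Venn partition counts of significant metabolite ids {only_mc, only_mt, both}."""
    sig_mc = {r.metabolite_id for r in diff_mc if r.significant}
    sig_mt = {r.metabolite_id for r in diff_mt if r.significant}
    both = sig_mc & sig_mt
    return {"only_mc": len(sig_mc - both), "only_mt": len(sig_mt - both), "both": len(both)}


@dataclass(frozen=True)
class ReversalBiomarker:
    metabolite_id: str
    direction_mc: int
    direction_mt: int


def find_reversed(
    diff_mc: Sequence[DifferentialResult], diff_mt: Sequence[DifferentialResult]
) -> list[ReversalBiomarker]:
    """Metabolites significant in both comparisons with opposite directions.

    ``diff_mc`` is model vs control, ``diff_mt`` treatment vs model; a
    reversal means the treatment pushes the disease-altered level back, i.e.
    direction_mt == -direction_mc (both nonzero).  Output sorted by id.
    """
    mc = {r.metabolite_id: r for r in diff_mc}
    mt = {r.metabolite_id: r for r in diff_mt}
    if set(mc) != set(mt):
        raise ValueError("both result lists must cover the same metabolite universe")
    out = []
    for met in sorted(mc):
        a, b = mc[met], mt[met]
        if a.significant and b.significant and a.direction != 0 and a.direction == -b.direction:
            out.append(ReversalBiomarker(met, a.direction, b.direction))
    return out
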