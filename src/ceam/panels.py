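"""Construction of cell-type-specific CpG panels from purified-nuclei methylomes.

Panels are built from beta-value matrices of FANS-sorted nuclear populations
(NeuN+ neurons, IRF8+ microglia, SOX10+ oligodendrocytes, and an
astrocyte-enriched triple-negative fraction) measured in two independent
cohorts. Three progressively relaxed specificity levels are defined:

* **high** — a CpG shows intermediate median methylation (0.1 < beta < 0.9)
  in exactly one cell type, every other cell type is hypo- or
  hypermethylated, and the target median differs from every other cell
  type's median by at least 0.1;
* **medium** — a CpG is intermediate in one to three cell types (at least
  one cell type must be extreme) and is annotated to every intermediate
  cell type;
* **low** — a CpG is intermediate in a cell type and significantly
  different (Bonferroni-adjusted p < 0.05) from all three other cell types
  under a linear mixed model on M-values adjusting for age and sex with a
  donor random intercept; CpGs from the high and medium levels are carried
  over regardless.

All criteria are evaluated within each cohort independently and the
per-cohort panels are intersected, so a panel CpG must satisfy its level's
criteria in both cohorts.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.tools.sm_exceptions import ConvergenceWarning

logger = logging.getLogger(__name__)

CELL_TYPES: tuple[str, ...] = ("NEU", "MG", "OLIG", "AST")
PAIRWISE_CONTRASTS: tuple[tuple[str, str], ...] = tuple(
    itertools.combinations(CELL_TYPES, 2)
)
SPECIFICITY_LEVELS: tuple[str, ...] = ("high", "medium", "low")

#: strict bounds of the "intermediate" methylation band
INTERMEDIATE_LOW = 0.1
INTERMEDIATE_HIGH = 0.9
#: minimum median-methylation gap between the target and every other cell
#: type at the high-specificity level
MEDIAN_GAP = 0.1
#: absolute tolerance for the gap comparison, so a gap of exactly 0.1 passes
#: despite binary-float rounding (0.15 - 0.05 != 0.1 exactly)
GAP_TOL = 1e-9
#: number of pairwise cell-type comparisons per CpG (Bonferroni family)
BONFERRONI_FACTOR = 6
DEFAULT_ALPHA = 0.05
#: clamp bound for the beta -> M logit transform
M_EPSILON = 1e-6

METADATA_COLUMNS = ("sample_id", "donor_id", "cell_type", "age", "sex", "cohort")


class PanelError(ValueError):
    """Raised when inputs violate the panel-construction contracts."""


# ---------------------------------------------------------------------------
# input validation
# ---------------------------------------------------------------------------

def validate_beta_matrix(betas: pd.DataFrame) -> pd.DataFrame:
    """Validate a CpG x sample beta matrix.

    Values must lie in [0, 1] with no missing entries; CpG and sample
    identifiers must be unique. Returns the validated frame unchanged.
    """
    if betas.index.has_duplicates:
        dups = betas.index[betas.index.duplicated()].unique().tolist()[:5]
        raise PanelError(f"duplicate CpG identifiers: {dups}")
    if betas.columns.has_duplicates:
        dups = betas.columns[betas.columns.duplicated()].unique().tolist()[:5]
        raise PanelError(f"duplicate sample identifiers: {dups}")
    values = betas.to_numpy(dtype=float, copy=False)
    if np.isnan(values).any():
        n_missing = int(np.isnan(values).sum())
        raise PanelError(
            f"beta matrix contains {n_missing} missing values; "
            "imputation is refused — supply a complete matrix"
        )
    if values.min() < 0.0 or values.max() > 1.0:
        raise PanelError(
            f"beta values outside [0, 1]: range "
            f"[{values.min():.4g}, {values.max():.4g}]"
        )
    return betas


def validate_metadata(meta: pd.DataFrame, betas: pd.DataFrame | None = None) -> pd.DataFrame:
    """Validate sample metadata and, optionally, its match to a beta matrix."""
    missing_cols = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing_cols:
        raise PanelError(f"metadata missing required columns: {missing_cols}")
    bad_cells = set(meta["cell_type"]) - set(CELL_TYPES)
    if bad_cells:
        raise PanelError(
            f"unknown cell_type labels {sorted(bad_cells)}; expected {CELL_TYPES}"
        )
    bad_sex = set(meta["sex"]) - {"F", "M"}
    if bad_sex:
        raise PanelError(f"unknown sex labels {sorted(bad_sex)}; expected F/M")
    per_cohort = meta.groupby("cohort")["sample_id"]
    if (per_cohort.nunique() != per_cohort.size()).any():
        raise PanelError("duplicate sample_id within a cohort")
    if meta[["age"]].isna().any().any():
        raise PanelError("missing covariate values in metadata")
    if betas is not None:
        unmatched = set(betas.columns) - set(meta["sample_id"])
        if unmatched:
            raise PanelError(
                f"samples without metadata: {sorted(unmatched)[:5]}"
            )
    return meta


# ---------------------------------------------------------------------------
# panel container
# ---------------------------------------------------------------------------

@dataclass
class CellTypePanel:
    """A per-specificity mapping from cell type to a set of CpG identifiers."""

    specificity: str
    assignments: dict[str, frozenset[str]]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.specificity not in SPECIFICITY_LEVELS:
            raise PanelError(
                f"unknown specificity {self.specificity!r}; "
                f"expected one of {SPECIFICITY_LEVELS}"
            )
        self.assignments = {
            c: frozenset(self.assignments.get(c, frozenset())) for c in CELL_TYPES
        }
        if self.specificity == "high":
            self.check_disjoint()

    def check_disjoint(self) -> None:
        """High-specificity sets must be pairwise disjoint (exclusivity)."""
        for a, b in PAIRWISE_CONTRASTS:
            shared = self.assignments[a] & self.assignments[b]
            if shared:
                raise PanelError(
                    f"high-specificity sets for {a} and {b} share CpGs, "
                    f"e.g. {sorted(shared)[:3]}"
                )

    def set_for(self, cell_type: str) -> frozenset[str]:
        return self.assignments[cell_type]

    def all_cpgs(self) -> frozenset[str]:
        out: frozenset[str] = frozenset()
        for s in self.assignments.values():
            out |= s
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CellTypePanel):
            return NotImplemented
        return (
            self.specificity == other.specificity
            and self.assignments == other.assignments
        )


# ---------------------------------------------------------------------------
# median profiles and the beta -> M transform
# ---------------------------------------------------------------------------

def compute_median_profile(betas: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Per-CpG, per-cell-type median beta within one cohort.

    Returns a CpG x cell-type frame with exactly the four cell-type
    columns. Requires at least two samples per cell type.
    """
    validate_beta_matrix(betas)
    validate_metadata(meta, betas)
    meta = meta.set_index("sample_id").loc[list(betas.columns)]
    medians = {}
    for cell in CELL_TYPES:
        cols = meta.index[meta["cell_type"] == cell]
        if len(cols) < 2:
            raise PanelError(
                f"cell type {cell} has {len(cols)} samples; need at least 2"
            )
        medians[cell] = betas[cols].median(axis=1)
    return pd.DataFrame(medians, index=betas.index)[list(CELL_TYPES)]


def beta_to_m(beta, epsilon: float = M_EPSILON):
    """Logit2 transform M = log2(beta / (1 - beta)), clamped away from 0/1.

    The clamp ``beta' = min(max(beta, epsilon), 1 - epsilon)`` keeps the
    transform finite; it is monotone in beta and antisymmetric about 0.5.
    """
    if not 0.0 < epsilon < 0.5:
        raise PanelError(f"epsilon must be in (0, 0.5); got {epsilon}")
    clamped = np.clip(np.asarray(beta, dtype=float), epsilon, 1.0 - epsilon)
    result = np.log2(clamped / (1.0 - clamped))
    if np.isscalar(beta) or np.ndim(beta) == 0:
        return float(result)
    if isinstance(beta, pd.DataFrame):
        return pd.DataFrame(result, index=beta.index, columns=beta.columns)
    return result


# ---------------------------------------------------------------------------
# threshold classifiers (high / medium)
# ---------------------------------------------------------------------------

def _check_profile(profile: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CELL_TYPES if c not in profile.columns]
    if missing:
        raise PanelError(f"median profile missing cell types: {missing}")
    return profile[list(CELL_TYPES)]


def _intermediate(profile: pd.DataFrame) -> pd.DataFrame:
    """Strictly-open intermediate band: 0.1 < median < 0.9."""
    return (profile > INTERMEDIATE_LOW) & (profile < INTERMEDIATE_HIGH)


def _classify_high_one_cohort(
    profile: pd.DataFrame, gap: float = MEDIAN_GAP
) -> dict[str, set[str]]:
    profile = _check_profile(profile)
    inter = _intermediate(profile)
    assignments: dict[str, set[str]] = {}
    for cell in CELL_TYPES:
        others = [o for o in CELL_TYPES if o != cell]
        exclusive = inter[cell] & ~inter[others].any(axis=1)
        gap_ok = (
            profile[others].sub(profile[cell], axis=0).abs() >= gap - GAP_TOL
        ).all(axis=1)
        assignments[cell] = set(profile.index[exclusive & gap_ok])
    return assignments


def classify_high(
    profile_a: pd.DataFrame,
    profile_b: pd.DataFrame,
    gap: float = MEDIAN_GAP,
) -> CellTypePanel:
    """High-specificity classification, intersected across the two cohorts.

    A CpG is assigned to cell type ``c`` iff, in each cohort independently,
    ``c`` is the only cell type with intermediate median methylation and all
    other medians differ from the target median by at least ``gap``.
    """
    a = _classify_high_one_cohort(profile_a, gap)
    b = _classify_high_one_cohort(profile_b, gap)
    assignments = {c: frozenset(a[c] & b[c]) for c in CELL_TYPES}
    return CellTypePanel(
        "high", assignments, provenance={"rule": "per-cohort-then-intersect"}
    )


def _classify_medium_one_cohort(
    profile: pd.DataFrame, require_gap: bool, gap: float
) -> dict[str, set[str]]:
    profile = _check_profile(profile)
    inter = _intermediate(profile)
    n_inter = inter.sum(axis=1)
    eligible = (n_inter >= 1) & (n_inter <= 3)
    assignments: dict[str, set[str]] = {}
    for cell in CELL_TYPES:
        mask = eligible & inter[cell]
        if require_gap:
            others = [o for o in CELL_TYPES if o != cell]
            extreme = ~inter[others]
            diff_ok = (
                profile[others].sub(profile[cell], axis=0).abs() >= gap - GAP_TOL
            )
            # gap enforced only against the extreme cell types
            mask &= (diff_ok | ~extreme).all(axis=1)
        assignments[cell] = set(profile.index[mask])
    return assignments


def classify_medium(
    profile_a: pd.DataFrame,
    profile_b: pd.DataFrame,
    require_gap: bool = False,
    gap: float = MEDIAN_GAP,
) -> CellTypePanel:
    """Medium-specificity classification, intersected across cohorts.

    A CpG is annotated to every cell type with intermediate median in both
    cohorts, provided one to three cell types are intermediate (so at least
    one is extreme) in each cohort. Multi-annotation is permitted; the
    result is a superset of the high panel per cell type. ``require_gap``
    optionally also demands the 0.1 median gap against extreme cell types.
    """
    a = _classify_medium_one_cohort(profile_a, require_gap, gap)
    b = _classify_medium_one_cohort(profile_b, require_gap, gap)
    assignments = {c: frozenset(a[c] & b[c]) for c in CELL_TYPES}
    return CellTypePanel(
        "medium", assignments, provenance={"rule": "per-cohort-then-intersect"}
    )


# ---------------------------------------------------------------------------
# mixed-model pairwise contrasts (low level)
# ---------------------------------------------------------------------------

def pairwise_mixed_contrasts(
    mvalues: pd.DataFrame,
    meta: pd.DataFrame,
    bonferroni_factor: int = BONFERRONI_FACTOR,
    show_progress: bool = False,
) -> pd.DataFrame:
    """Six pairwise cell-type contrasts per CpG from a linear mixed model.

    For each CpG the model ``M ~ cell_type + age + sex`` with a random
    intercept per donor is fit by REML; the six pairwise cell-type
    differences are tested and Bonferroni-adjusted within the CpG
    (``p_bonf = min(1, bonferroni_factor * p_raw)``). Donors must appear
    with multiple cell types for the random intercept to be identifiable;
    when the mixed fit fails or is degenerate a fixed-effects fallback with
    donor as a fixed covariate is used and flagged in the ``method`` column.
    CpGs where both routes fail are reported with ``method='failed'`` and
    NaN p-values (they are then ineligible for the low-specificity route).

    Returns a tidy frame with columns ``cpg_id, cell_a, cell_b, estimate,
    p_raw, p_bonf, method``.
    """
    meta = validate_metadata(meta).set_index("sample_id").loc[list(mvalues.columns)]
    if meta.groupby("donor_id")["cell_type"].nunique().max() < 2:
        logger.warning(
            "no donor contributes more than one cell type; "
            "the donor random intercept is not identifiable"
        )

    cell_idx = {c: i for i, c in enumerate(CELL_TYPES)}
    n = len(meta)
    # fixed-effects design: intercept, 3 cell dummies (NEU baseline), age, sex
    X = np.zeros((n, 6))
    X[:, 0] = 1.0
    for j, cell in enumerate(CELL_TYPES[1:], start=1):
        X[:, j] = (meta["cell_type"] == cell).to_numpy(float)
    # age is standardized for numerical conditioning; this leaves the
    # cell-type contrasts (and their p-values) unchanged
    age = meta["age"].to_numpy(float)
    X[:, 4] = (age - age.mean()) / (age.std() if age.std() > 0 else 1.0)
    X[:, 5] = (meta["sex"] == "M").to_numpy(float)
    groups = meta["donor_id"].to_numpy()

    # contrast rows: effect of cell c is 0 for the baseline, else its dummy
    effect_rows = {CELL_TYPES[0]: np.zeros(6)}
    for j, cell in enumerate(CELL_TYPES[1:], start=1):
        row = np.zeros(6)
        row[j] = 1.0
        effect_rows[cell] = row
    contrast_matrix = np.vstack(
        [effect_rows[a] - effect_rows[b] for a, b in PAIRWISE_CONTRASTS]
    )

    records = []
    exog = pd.DataFrame(
        X, columns=["const", "MG", "OLIG", "AST", "age", "sex_M"],
        index=mvalues.columns,
    )
    iterator = mvalues.index
    if show_progress:
        iterator = list(iterator)
    for cpg in iterator:
        endog = mvalues.loc[cpg].to_numpy(float)
        estimates = pvals = None
        method = "mixed_reml"
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                warnings.simplefilter("ignore", RuntimeWarning)
                warnings.simplefilter("ignore", UserWarning)
                model = MixedLM(endog, exog.to_numpy(), groups=groups)
                fit = model.fit(reml=True, maxiter=200)
            if not np.all(np.isfinite(fit.bse_fe)):
                raise np.linalg.LinAlgError("non-finite standard errors")
            tt = fit.t_test(contrast_matrix)
            estimates = np.atleast_1d(tt.effect)
            pvals = np.atleast_1d(tt.pvalue)
        except Exception:
            estimates = pvals = None
        if pvals is None or not np.all(np.isfinite(pvals)):
            estimates, pvals, method = _fixed_effect_fallback(
                endog, X, groups, contrast_matrix
            )
        if pvals is None:
            method = "failed"
            estimates = np.full(6, np.nan)
            pvals = np.full(6, np.nan)
            logger.warning("contrast fit failed for CpG %s; excluded", cpg)
        p_bonf = np.minimum(1.0, bonferroni_factor * pvals)
        for (ca, cb), est, p, pb in zip(
            PAIRWISE_CONTRASTS, estimates, pvals, p_bonf
        ):
            records.append((cpg, ca, cb, est, p, pb, method))
    return pd.DataFrame(
        records,
        columns=["cpg_id", "cell_a", "cell_b", "estimate", "p_raw", "p_bonf", "method"],
    )


def _fixed_effect_fallback(endog, X, groups, contrast_matrix):
    """OLS with donor as a fixed covariate when the mixed fit degenerates."""
    from scipy import stats as sps

    donors = pd.unique(groups)
    if len(donors) > 1:
        dummies = np.column_stack(
            [(groups == d).astype(float) for d in donors[1:]]
        )
        Xf = np.hstack([X, dummies])
        L = np.hstack([contrast_matrix, np.zeros((6, len(donors) - 1))])
    else:
        Xf, L = X, contrast_matrix
    try:
        beta, _, rank, _ = np.linalg.lstsq(Xf, endog, rcond=None)
        dof = Xf.shape[0] - rank
        if dof <= 0:
            return None, None, "failed"
        resid = endog - Xf @ beta
        sigma2 = float(resid @ resid) / dof
        cov = sigma2 * np.linalg.pinv(Xf.T @ Xf)
        est = L @ beta
        se = np.sqrt(np.einsum("ij,jk,ik->i", L, cov, L))
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = np.where(se > 0, est / se, 0.0)
        pvals = 2.0 * sps.t.sf(np.abs(tstat), dof)
        return est, pvals, "ols_fixed_donor"
    except np.linalg.LinAlgError:
        return None, None, "failed"


def _low_statistical_route(
    profile: pd.DataFrame, contrasts: pd.DataFrame, alpha: float
) -> dict[str, set[str]]:
    """Per-cohort low-specificity candidates via the mixed-model criterion."""
    profile = _check_profile(profile)
    inter = _intermediate(profile)
    ok = contrasts.dropna(subset=["p_bonf"])
    ok = ok[ok["method"] != "failed"]
    assignments: dict[str, set[str]] = {c: set() for c in CELL_TYPES}
    for cell in CELL_TYPES:
        involving = ok[(ok["cell_a"] == cell) | (ok["cell_b"] == cell)]
        grouped = involving.groupby("cpg_id")["p_bonf"]
        complete = grouped.count() == 3
        significant = grouped.max() < alpha
        passing = set(complete.index[complete & significant])
        candidates = set(profile.index[inter[cell]])
        dropped = {
            c for c in candidates
            if c in set(contrasts["cpg_id"]) and c not in set(involving["cpg_id"])
        }
        if dropped:
            logger.warning(
                "%d intermediate CpGs lack contrasts for %s and were excluded",
                len(dropped), cell,
            )
        assignments[cell] = candidates & passing
    return assignments


def classify_low(
    profile_a: pd.DataFrame,
    profile_b: pd.DataFrame,
    contrasts_a: pd.DataFrame,
    contrasts_b: pd.DataFrame,
    high: CellTypePanel,
    medium: CellTypePanel,
    alpha: float = DEFAULT_ALPHA,
) -> CellTypePanel:
    """Low-specificity classification.

    A CpG is annotated to cell type ``c`` iff its median is intermediate and
    all three contrasts involving ``c`` reach Bonferroni significance in
    both cohorts — or the CpG already belongs to the high or medium panel
    for ``c``, in which case it is carried over regardless.
    """
    a = _low_statistical_route(profile_a, contrasts_a, alpha)
    b = _low_statistical_route(profile_b, contrasts_b, alpha)
    assignments = {
        c: frozenset(
            (a[c] & b[c]) | high.assignments[c] | medium.assignments[c]
        )
        for c in CELL_TYPES
    }
    return CellTypePanel(
        "low", assignments, provenance={"alpha": alpha}
    )


def intersect_cohorts(panel_a: CellTypePanel, panel_b: CellTypePanel) -> CellTypePanel:
    """Per-cell-type set intersection of two same-specificity panels."""
    if panel_a.specificity != panel_b.specificity:
        raise PanelError(
            f"specificity mismatch: {panel_a.specificity} vs {panel_b.specificity}"
        )
    assignments = {}
    for cell in CELL_TYPES:
        shared = panel_a.assignments[cell] & panel_b.assignments[cell]
        if not shared and (panel_a.assignments[cell] or panel_b.assignments[cell]):
            logger.warning("cohort panels for %s are disjoint; empty set", cell)
        assignments[cell] = shared
    return CellTypePanel(
        panel_a.specificity, assignments, provenance={"intersected": True}
    )


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def build_panels(
    betas_a: pd.DataFrame,
    meta_a: pd.DataFrame,
    betas_b: pd.DataFrame,
    meta_b: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    bonferroni_factor: int = BONFERRONI_FACTOR,
    medium_gap: bool = False,
    epsilon: float = M_EPSILON,
) -> dict[str, CellTypePanel]:
    """Build the three specificity panels from two purified-cell cohorts.

    Restricts to the CpG universe shared by both cohorts, computes
    per-cohort median profiles, applies the threshold classifiers, fits the
    mixed-model contrasts on M-values for the low-level candidates, and
    intersects everything across cohorts. Returns ``{level: CellTypePanel}``.
    """
    validate_beta_matrix(betas_a)
    validate_beta_matrix(betas_b)
    shared = betas_a.index.intersection(betas_b.index)
    if shared.empty:
        raise PanelError("the two cohorts share no CpGs")
    betas_a = betas_a.loc[shared]
    betas_b = betas_b.loc[shared]

    profile_a = compute_median_profile(betas_a, meta_a)
    profile_b = compute_median_profile(betas_b, meta_b)

    high = classify_high(profile_a, profile_b)
    medium = classify_medium(profile_a, profile_b, require_gap=medium_gap)

    # the statistical route only applies to CpGs intermediate somewhere in
    # both cohorts; restrict the costly mixed-model fits to those, minus
    # CpGs whose full annotation is already settled by carry-over
    inter_any = (
        _intermediate(profile_a).any(axis=1) & _intermediate(profile_b).any(axis=1)
    )
    candidates = shared[inter_any.loc[shared]]
    m_a = beta_to_m(betas_a.loc[candidates], epsilon)
    m_b = beta_to_m(betas_b.loc[candidates], epsilon)
    contrasts_a = pairwise_mixed_contrasts(m_a, meta_a, bonferroni_factor)
    contrasts_b = pairwise_mixed_contrasts(m_b, meta_b, bonferroni_factor)

    low = classify_low(
        profile_a, profile_b, contrasts_a, contrasts_b, high, medium, alpha
    )
    for level, panel in (("high", high), ("medium", medium), ("low", low)):
        panel.provenance["shared_universe_size"] = int(len(shared))
        sizes = {c: len(panel.assignments[c]) for c in CELL_TYPES}
        logger.info("%s-specificity panel sizes: %s", level, sizes)
    return {"high": high, "medium": medium, "low": low}
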