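"""Over-representation analysis of EWAS DMP lists against cell-type CpG panels.

Given an input list of differentially methylated positions (DMPs), a
background CpG universe, and a cell-type-specific CpG panel, each cell
type's set is tested for over-representation with a one-sided exact
hypergeometric test on the 2x2 table

    a = input DMPs in the set          b = input DMPs outside the set
    c = non-input background in set    d = non-input background outside

The odds ratio is ``a*d / (b*c)`` when all cells are positive; when any
cell is zero a Haldane-Anscombe correction (0.5 added to every cell) is
applied. When the input overlaps the set in zero CpGs (``a = 0``) the
reported odds ratio is 0 with a flag — a reporting convention, not an
estimate — while the corrected value is retained for diagnostics.
Benjamini-Hochberg adjustment is applied across the four cell types within
one specificity level.

A competitive permutation null is provided: permuted input sets are drawn
from the background matched on probe design type, CpG-island context and
gene context, preserving the input's joint annotation composition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .panels import CELL_TYPES, CellTypePanel

logger = logging.getLogger(__name__)

ANNOTATION_FACTORS = ("probe_design", "island_context", "gene_context")
#: deterministic coarsening order when a matching stratum is too small
FALLBACK_ORDER = ("gene_context", "island_context", "probe_design")


class EnrichmentError(ValueError):
    """Raised when ORA inputs violate the contracts."""


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 overlap table between an input CpG list and a panel set."""

    a: int  # input DMPs in set
    b: int  # input DMPs not in set
    c: int  # non-input background CpGs in set
    d: int  # non-input background CpGs not in set

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise EnrichmentError(f"cell {name} must be a non-negative integer")

    @property
    def input_size(self) -> int:
        return self.a + self.b

    @property
    def set_size(self) -> int:
        return self.a + self.c

    @property
    def background_size(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass
class EnrichmentResult:
    cell_type: str
    specificity: str
    overlap_n: int
    set_size: int
    input_size: int
    background_size: int
    odds_ratio: float
    p_value: float
    fdr: float
    zero_overlap: bool
    odds_ratio_corrected: float = float("nan")


@dataclass
class PermutationNullResult:
    cell_type: str
    observed_or: float
    permuted_ors: np.ndarray
    empirical_p: float
    n_perm: int
    seed: int | None
    fallback_log: list = field(default_factory=list)
    #: the first permuted set, retained so matched composition can be audited
    example_permuted_set: set = field(default_factory=set)


# ---------------------------------------------------------------------------
# contingency, odds ratio, exact test, FDR
# ---------------------------------------------------------------------------

def build_contingency(
    input_cpgs: set[str],
    background: set[str],
    panel_set: set[str],
    on_missing: str = "error",
) -> ContingencyTable:
    """Count the 2x2 table; the panel set is intersected with the background.

    Input CpGs must be a subset of the background; ``on_missing='drop'``
    demotes violations to a logged warning and drops the offenders.
    """
    input_cpgs, background, panel_set = (
        set(input_cpgs), set(background), set(panel_set)
    )
    if not input_cpgs:
        raise EnrichmentError("input CpG list is empty")
    if not background:
        raise EnrichmentError("background CpG list is empty")
    missing = input_cpgs - background
    if missing:
        if on_missing == "drop":
            logger.warning(
                "%d input CpGs absent from background were dropped (e.g. %s)",
                len(missing), sorted(missing)[:3],
            )
            input_cpgs -= missing
            if not input_cpgs:
                raise EnrichmentError("no input CpGs remain after dropping")
        else:
            raise EnrichmentError(
                f"{len(missing)} input CpGs absent from background, "
                f"e.g. {sorted(missing)[:5]}; pass on_missing='drop' to demote"
            )
    set_in_bg = panel_set & background
    a = len(input_cpgs & set_in_bg)
    b = len(input_cpgs) - a
    c = len(set_in_bg) - a
    d = len(background) - len(input_cpgs) - c
    return ContingencyTable(a, b, c, d)


def odds_ratio_ha(table: ContingencyTable) -> tuple[float, bool, float]:
    """Odds ratio with a conditional Haldane-Anscombe correction.

    Returns ``(reported_or, zero_overlap_flag, corrected_or)``. With all
    cells positive the plain cross-product ratio is used. When any cell is
    zero, 0.5 is added to every cell. When the overlap ``a`` is zero the
    reported value is 0 (flagged) while the corrected value is retained.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if min(a, b, c, d) > 0:
        value = (a * d) / (b * c)
        return value, False, value
    corrected = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    if a == 0:
        return 0.0, True, corrected
    return corrected, False, corrected


def enrichment_p(table: ContingencyTable, alternative: str = "greater") -> float:
    """Exact hypergeometric tail probability for the 2x2 table.

    One-sided (enrichment) by default: ``P(X >= a)`` with all margins
    fixed. ``alternative='two-sided'`` gives Fisher's exact two-sided p.
    """
    if alternative == "greater":
        p = stats.hypergeom.sf(
            table.a - 1, table.background_size, table.set_size, table.input_size
        )
        return float(min(1.0, max(p, np.nextafter(0, 1))))
    if alternative == "two-sided":
        _, p = stats.fisher_exact(
            [[table.a, table.b], [table.c, table.d]], alternative="two-sided"
        )
        return float(p)
    raise EnrichmentError(f"unknown alternative {alternative!r}")


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise EnrichmentError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# the ORA itself
# ---------------------------------------------------------------------------

def run_ora(
    input_cpgs,
    background,
    panel: CellTypePanel,
    alternative: str = "greater",
    on_missing: str = "error",
) -> list[EnrichmentResult]:
    """One enrichment row per cell type, FDR-adjusted within the panel level."""
    input_cpgs = set(input_cpgs)
    background = set(background)
    rows = []
    for cell in CELL_TYPES:
        table = build_contingency(
            input_cpgs, background, set(panel.assignments[cell]), on_missing
        )
        reported, flag, corrected = odds_ratio_ha(table)
        p = enrichment_p(table, alternative)
        rows.append(
            EnrichmentResult(
                cell_type=cell,
                specificity=panel.specificity,
                overlap_n=table.a,
                set_size=table.set_size,
                input_size=table.input_size,
                background_size=table.background_size,
                odds_ratio=reported,
                p_value=p,
                fdr=np.nan,
                zero_overlap=flag,
                odds_ratio_corrected=corrected,
            )
        )
    adjusted = bh_fdr([r.p_value for r in rows])
    for r, q in zip(rows, adjusted):
        r.fdr = float(q)
    return rows


def results_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    """Tidy frame mirroring the TSV output schema."""
    return pd.DataFrame(
        [
            {
                "cell_type": r.cell_type,
                "specificity": r.specificity,
                "overlap_n": r.overlap_n,
                "set_size": r.set_size,
                "input_size": r.input_size,
                "background_size": r.background_size,
                "odds_ratio": r.odds_ratio,
                "p_value": r.p_value,
                "fdr": r.fdr,
                "zero_overlap": r.zero_overlap,
            }
            for r in results
        ]
    )


def overlap_decomposition(
    input_cpgs, panel: CellTypePanel
) -> dict[tuple[str, ...], int]:
    """Counts of input CpGs per cell-type combination.

    Medium- and low-specificity CpGs may be annotated to several cell
    types; this decomposes the input overlap into shared-vs-unique counts
    per combination (keys are sorted cell-type tuples).
    """
    input_cpgs = set(input_cpgs)
    counts: dict[tuple[str, ...], int] = {}
    for r in range(1, len(CELL_TYPES) + 1):
        for combo in combinations(CELL_TYPES, r):
            in_all = set.intersection(
                *[set(panel.assignments[c]) for c in combo]
            )
            out_of_rest = set().union(
                *[set(panel.assignments[c]) for c in CELL_TYPES if c not in combo]
            )
            exact = (in_all - out_of_rest) & input_cpgs
            if exact:
                counts[combo] = len(exact)
    return counts


# ---------------------------------------------------------------------------
# matched permutation null
# ---------------------------------------------------------------------------

def _stratum_labels(annotation: pd.DataFrame, level: int) -> pd.Series:
    """Joint stratum label using the first ``level`` coarsening steps dropped."""
    keep = [f for f in ANNOTATION_FACTORS if f not in FALLBACK_ORDER[:level]]
    if not keep:
        return pd.Series("all", index=annotation.index)
    return annotation[keep].astype(str).agg("|".join, axis=1)


def matched_permutation_null(
    input_cpgs,
    background,
    panel_set,
    annotation: pd.DataFrame,
    n_perm: int = 1000,
    seed: int | None = None,
    cell_type: str = "",
) -> PermutationNullResult:
    """Competitive null from annotation-matched permuted input sets.

    Each permuted set draws, without replacement within each joint stratum
    of (probe design, island context, gene context), as many background
    probes as the input holds in that stratum; the Haldane-Anscombe odds
    ratio against the panel set is recorded. If a stratum holds fewer
    background probes than required, matching deterministically coarsens by
    dropping gene context, then island context (logged). The empirical p is
    ``(1 + #{permuted OR >= observed OR}) / (n_perm + 1)``.
    """
    if n_perm < 1:
        raise EnrichmentError("n_perm must be >= 1")
    input_cpgs = set(input_cpgs)
    background = set(background)
    panel_set = set(panel_set) & background
    if annotation.index.name != "cpg_id" and "cpg_id" in annotation.columns:
        annotation = annotation.set_index("cpg_id")
    uncovered = background - set(annotation.index)
    if uncovered:
        raise EnrichmentError(
            f"annotation does not cover {len(uncovered)} background CpGs, "
            f"e.g. {sorted(uncovered)[:3]}"
        )
    ann = annotation.loc[sorted(background)]

    observed_table = build_contingency(input_cpgs, background, panel_set)
    observed_or, _, _ = odds_ratio_ha(observed_table)

    # Resolve, once, the stratum each input CpG is matched in. Because the
    # input is a subset of the background the exact joint stratum always
    # holds enough probes; the coarsening fallback guards subsetted or
    # inconsistent annotations.
    fallback_log: list[str] = []
    draw_plan: list[tuple[np.ndarray, int]] = []  # (candidate row indices, k)
    bg_ids = ann.index.to_numpy()
    in_set = np.fromiter((c in panel_set for c in bg_ids), bool, len(bg_ids))
    remaining = sorted(input_cpgs)
    for level in range(len(FALLBACK_ORDER) + 1):
        if not remaining:
            break
        labels = _stratum_labels(ann, level)
        bg_counts = labels.value_counts()
        counts = labels.loc[remaining].value_counts()
        unmet: set[str] = set()
        for stratum, k in counts.items():
            if int(bg_counts.get(stratum, 0)) >= k:
                draw_plan.append(
                    (np.flatnonzero(labels.to_numpy() == stratum), int(k))
                )
            else:
                unmet.add(stratum)
        if not unmet:
            remaining = []
            break
        if level == len(FALLBACK_ORDER):
            raise EnrichmentError(
                "cannot match some input CpGs even on the full background"
            )
        fallback_log.append(
            f"{len(unmet)} strata too small at matching level {level}; "
            f"dropping {FALLBACK_ORDER[level]} from matching"
        )
        logger.warning("%s", fallback_log[-1])
        remaining = [c for c in remaining if labels.loc[c] in unmet]

    rng = np.random.default_rng(seed)
    permuted = np.empty(n_perm)
    example_permuted_set: set[str] = set()
    n_input = len(input_cpgs)
    n_bg = len(bg_ids)
    n_set = int(in_set.sum())
    for i in range(n_perm):
        hit = 0
        for idx, k in draw_plan:
            chosen = rng.choice(idx, size=k, replace=False)
            hit += int(in_set[chosen].sum())
            if i == 0:
                example_permuted_set.update(bg_ids[chosen])
        a = hit
        b = n_input - a
        c = n_set - a
        d = n_bg - n_input - c
        permuted[i], _, _ = odds_ratio_ha(ContingencyTable(a, b, c, d))
    empirical_p = (1 + int(np.sum(permuted >= observed_or))) / (n_perm + 1)
    result = PermutationNullResult(
        cell_type=cell_type,
        observed_or=observed_or,
        permuted_ors=permuted,
        empirical_p=float(empirical_p),
        n_perm=n_perm,
        seed=seed,
        fallback_log=fallback_log,
    )
    result.example_permuted_set = example_permuted_set
    return result


def permuted_stratum_counts(
    permuted_set, annotation: pd.DataFrame
) -> pd.Series:
    """Joint-stratum counts of a CpG set (for checking matched composition)."""
    if annotation.index.name != "cpg_id" and "cpg_id" in annotation.columns:
        annotation = annotation.set_index("cpg_id")
    return _stratum_labels(annotation.loc[sorted(permuted_set)], 0).value_counts()
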