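"""Pseudo-bulk DNA methylation simulation and the two validation experiments.

Synthetic bulk methylomes are built as convex combinations of four
simulated cell-type-specific profiles. Each CpG belongs either to one
cell type's simulated "set" — intermediate mean methylation (0.15-0.85)
in the target cell type, extreme (0.01-0.09 or 0.91-0.99) in the others —
or to the background, where all four cell-type means are intermediate.
Per-CpG draws come from a normal distribution truncated to [0, 1] whose
spread shrinks towards the boundaries:

    SD* = SD * (1 - |0.5 - mu| / 0.5)

with SD sampled uniformly from [0, 0.1], emulating the heteroskedasticity
of array beta values. Per-sample cell-type mixing weights are Dirichlet
draws on the 4-simplex.

Two experiments exercise the enrichment workflow:

* **composition shift** — disease samples receive Dirichlet weights with
  three cell types up-weighted (a relative neuronal reduction); DMPs are
  called by per-CpG linear regression on group, once without and once with
  the mixing weights as covariates, while Gaussian noise of increasing SD
  corrupts the weights used for correction; set enrichment is then scored
  by the ORA.
* **input size** — both groups share equal Dirichlet weights and a known
  number of DMPs (2..1024) is injected with a fixed allocation (50%
  neuron set, 20% microglia set, 0.1% each oligodendrocyte/astrocyte set,
  29.8% background); only the corrected analysis is run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri
from scipy import stats

from .enrich import bh_fdr, build_contingency, enrichment_p, odds_ratio_ha
from .panels import CELL_TYPES

logger = logging.getLogger(__name__)

BACKGROUND = "background"
DMP_CATEGORIES = CELL_TYPES + (BACKGROUND,)


class SimulationError(ValueError):
    """Raised when a simulation configuration or input is invalid."""


@dataclass
class SimulationConfig:
    """Parameters of the pseudo-bulk simulation experiments.

    Defaults mirror the published study conditions: 200,000 CpGs (a quarter
    of a preprocessed EPIC array), 250 samples per group, ten iterations,
    weight-noise SDs spanning 0-1.5, and the DMP grid 2..1024 in powers of
    two. ``set_fractions`` approximate the high-specificity panel's share
    of the array (about 6% in total, with the oligodendrocyte and
    astrocyte sets several-fold smaller). For test-scale runs lower
    ``n_cpgs`` (the experiments scale linearly in it).
    """

    n_cpgs: int = 200_000
    n_per_group: int = 250
    set_fractions: dict = field(
        default_factory=lambda: {"NEU": 0.025, "MG": 0.025, "OLIG": 0.006, "AST": 0.006}
    )
    alpha_control: tuple = (1.0, 1.0, 1.0, 1.0)
    alpha_disease: tuple = (1.0, 2.0, 2.0, 2.0)  # NEU relatively reduced
    noise_sds: tuple = (0.0, 0.3, 0.6, 0.9, 1.2, 1.5)
    n_iterations: int = 10
    dmp_counts: tuple = (2, 4, 8, 16, 32, 64, 128, 256, 512, 1024)
    dmp_allocation: dict = field(
        default_factory=lambda: {
            "NEU": 0.50, "MG": 0.20, "OLIG": 0.001, "AST": 0.001, BACKGROUND: 0.298,
        }
    )
    effect_delta: float = 0.2
    fdr_threshold: float = 0.05
    noise_mode: str = "proportional"
    seed: int | None = None

    def __post_init__(self) -> None:
        fr = self.set_fractions
        if any(v < 0 for v in fr.values()) or sum(fr.values()) >= 1:
            raise SimulationError("set_fractions must be >= 0 and sum to < 1")
        if abs(sum(self.dmp_allocation.values()) - 1.0) > 1e-9:
            raise SimulationError("dmp_allocation must sum to 1")
        for name in ("alpha_control", "alpha_disease"):
            alpha = getattr(self, name)
            if len(alpha) != 4 or any(a <= 0 for a in alpha):
                raise SimulationError(f"{name} must be 4 strictly positive values")
        if self.noise_mode not in ("proportional", "additive"):
            raise SimulationError("noise_mode must be 'proportional' or 'additive'")


@dataclass
class CpGSimSpecs:
    """Vectorized per-CpG generating parameters.

    ``mu`` and ``sd_star`` are (n_cpgs, 4) arrays ordered as CELL_TYPES;
    ``category`` holds the set membership ('NEU', ..., 'background').
    """

    cpg_ids: np.ndarray
    category: np.ndarray
    mu: np.ndarray
    sd: np.ndarray
    sd_star: np.ndarray

    def set_cpgs(self, cell_type: str) -> set[str]:
        return set(self.cpg_ids[self.category == cell_type])

    def panel_sets(self) -> dict[str, set[str]]:
        return {c: self.set_cpgs(c) for c in CELL_TYPES}


@dataclass
class PseudoBulkDataset:
    """Simulated bulk betas plus the ground truth that produced them."""

    bulk: np.ndarray  # (n_samples, n_cpgs)
    cpg_ids: np.ndarray
    group: np.ndarray  # 'control' / 'disease' per sample
    true_weights: np.ndarray  # (n_samples, 4)
    specs: CpGSimSpecs
    designated_dmps: set = field(default_factory=set)


# ---------------------------------------------------------------------------
# generating model
# ---------------------------------------------------------------------------

def sd_star_from(sd, mu):
    """Boundary-shrunk SD: SD* = SD * (1 - |0.5 - mu| / 0.5)."""
    return np.asarray(sd) * (1.0 - np.abs(0.5 - np.asarray(mu)) / 0.5)


def simulate_cpg_specs(config: SimulationConfig, rng: np.random.Generator) -> CpGSimSpecs:
    """Draw per-CpG categories, means, and heteroskedastic SDs.

    Per-category counts are ``round(fraction * n_cpgs)``. Set CpGs get a
    target mean uniform in [0.15, 0.85] and, in each other cell type, an
    extreme mean uniform in [0.01, 0.09] or [0.91, 0.99] (fair coin per
    cell type). Background CpGs draw all four means from [0.15, 0.85].
    """
    n = config.n_cpgs
    counts = {c: int(round(config.set_fractions.get(c, 0.0) * n)) for c in CELL_TYPES}
    n_set = sum(counts.values())
    if n_set > n:
        raise SimulationError("set fractions allocate more CpGs than available")
    category = np.array(
        [c for c in CELL_TYPES for _ in range(counts[c])]
        + [BACKGROUND] * (n - n_set),
        dtype=object,
    )
    cpg_ids = np.array([f"cpg{i:07d}" for i in range(n)], dtype=object)

    mu = rng.uniform(0.15, 0.85, size=(n, 4))
    for j, target in enumerate(CELL_TYPES):
        rows = np.flatnonzero(category == target)
        for k in range(4):
            if k == j:
                continue
            lo = rng.uniform(0.01, 0.09, size=len(rows))
            hi = rng.uniform(0.91, 0.99, size=len(rows))
            take_hi = rng.random(len(rows)) < 0.5
            mu[rows, k] = np.where(take_hi, hi, lo)
    sd = rng.uniform(0.0, 0.1, size=n)
    sd_star = sd_star_from(sd[:, None], mu)
    return CpGSimSpecs(cpg_ids, category, mu, sd, sd_star)


def _truncnorm_01(mu: np.ndarray, sd: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draws from N(mu, sd) truncated to [0, 1], elementwise over arrays.

    Inverse-CDF sampling: u ~ U(Phi(a), Phi(b)), x = mu + sd * Phi^-1(u).
    Entries with sd = 0 return mu exactly.
    """
    mu = np.asarray(mu, float)
    sd = np.asarray(sd, float)
    out = np.array(np.broadcast_to(mu, np.broadcast_shapes(mu.shape, sd.shape)))
    sd_b = np.broadcast_to(sd, out.shape)
    pos = sd_b > 0
    if pos.any():
        m, s = out[pos], sd_b[pos]
        lo = ndtr((0.0 - m) / s)
        hi = ndtr((1.0 - m) / s)
        u = lo + rng.random(m.shape) * (hi - lo)
        # guard the open-interval ends against rounding to exactly 0/1
        u = np.clip(u, 1e-15, 1 - 1e-15)
        out[pos] = np.clip(m + s * ndtri(u), 0.0, 1.0)
    return out


def sample_cell_profiles(
    specs: CpGSimSpecs, n_samples: int, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """One truncated-normal draw per (sample, CpG, cell type).

    Returns ``{cell_type: (n_samples, n_cpgs) array}``.
    """
    profiles = {}
    for j, cell in enumerate(CELL_TYPES):
        profiles[cell] = _truncnorm_01(
            specs.mu[None, :, j], specs.sd_star[None, :, j] * np.ones((n_samples, 1)), rng
        )
    return profiles


def draw_weights(n_samples: int, alpha, rng: np.random.Generator) -> np.ndarray:
    """Per-sample cell-type proportions: Dirichlet(alpha) rows on the simplex."""
    alpha = np.asarray(alpha, float)
    if alpha.ndim != 1 or np.any(alpha <= 0):
        raise SimulationError("alpha must be a vector of strictly positive values")
    return rng.dirichlet(alpha, size=n_samples)


def mix_pseudobulk(cell_profiles: dict[str, np.ndarray], weights: np.ndarray) -> np.ndarray:
    """Bulk beta = sum_c w_c * beta_c per (sample, CpG); convex combination."""
    shapes = {cell_profiles[c].shape for c in CELL_TYPES}
    if len(shapes) != 1:
        raise SimulationError("cell profiles have mismatched shapes")
    (shape,) = shapes
    if weights.shape != (shape[0], 4):
        raise SimulationError(
            f"weights shape {weights.shape} does not match {shape[0]} samples"
        )
    bulk = np.zeros(shape)
    for j, cell in enumerate(CELL_TYPES):
        bulk += weights[:, j : j + 1] * cell_profiles[cell]
    return bulk


def perturb_weights(
    weights: np.ndarray,
    noise_sd: float,
    rng: np.random.Generator,
    mode: str = "proportional",
) -> tuple[np.ndarray, float]:
    """Corrupt mixing weights with Gaussian noise; returns (perturbed, mean RMSE).

    ``proportional`` (default) scales the noise by the weight magnitude,
    ``w * (1 + N(0, sd))`` — at SD 0.6 this yields a mean RMSE of about
    0.12 on Dirichlet-mixed designs. ``additive`` adds ``N(0, sd)``
    directly. Either way negatives are floored at 0 and rows renormalized
    to sum 1 (an all-zero row becomes uniform 0.25s). The mean RMSE is the
    per-sample root-mean-square deviation over the four proportions,
    averaged over samples.
    """
    if noise_sd < 0:
        raise SimulationError("noise_sd must be >= 0")
    w = np.asarray(weights, float)
    if noise_sd == 0:
        return w.copy(), 0.0
    noise = rng.normal(0.0, noise_sd, size=w.shape)
    if mode == "proportional":
        perturbed = w * (1.0 + noise)
    elif mode == "additive":
        perturbed = w + noise
    else:
        raise SimulationError(f"unknown noise mode {mode!r}")
    perturbed = np.maximum(perturbed, 0.0)
    rowsum = perturbed.sum(axis=1, keepdims=True)
    zero_rows = rowsum[:, 0] == 0
    perturbed[zero_rows] = 0.25
    rowsum[zero_rows] = 1.0
    perturbed /= rowsum
    mean_rmse = float(np.sqrt(((w - perturbed) ** 2).mean(axis=1)).mean())
    return perturbed, mean_rmse


# ---------------------------------------------------------------------------
# DMP calling and injection
# ---------------------------------------------------------------------------

def call_dmps(
    bulk: np.ndarray,
    group: np.ndarray,
    composition: np.ndarray | None = None,
    fdr_threshold: float = 0.05,
    cpg_ids: np.ndarray | None = None,
) -> tuple[set[str], pd.DataFrame]:
    """Per-CpG ordinary least squares of bulk beta on the group indicator.

    ``composition`` optionally adds the mixing weights as covariates; since
    the four proportions sum to one, the last column is dropped to avoid
    collinearity. Fitting is vectorized across CpGs via a shared QR
    decomposition of the design. Returns the FDR-significant CpG set and a
    per-CpG table with the group coefficient, raw p, and BH-adjusted p.
    Constant CpG columns get p = 1.
    """
    bulk = np.asarray(bulk, float)
    n_samples, n_cpgs = bulk.shape
    g = np.asarray(
        [1.0 if x in (1, "disease", True) else 0.0 for x in group], float
    )
    if len(g) != n_samples:
        raise SimulationError("group labels do not match the number of samples")
    if len(np.unique(g)) < 2 or min((g == 1).sum(), (g == 0).sum()) < 2:
        raise SimulationError("need at least two samples per group")
    cols = [np.ones(n_samples), g]
    if composition is not None:
        composition = np.asarray(composition, float)
        if composition.shape[0] != n_samples:
            raise SimulationError("composition covariates do not match samples")
        cols.extend(composition[:, :-1].T)  # weights sum to 1: drop one column
    X = np.column_stack(cols)
    n, p = X.shape
    Q, R = np.linalg.qr(X)
    coef = np.linalg.solve(R, Q.T @ bulk)  # (p, n_cpgs)
    resid = bulk - X @ coef
    dof = n - p
    sigma2 = (resid**2).sum(axis=0) / dof
    Rinv = np.linalg.inv(R)
    xtx_inv_diag = (Rinv**2).sum(axis=1)  # diag of (X'X)^-1
    se = np.sqrt(sigma2 * xtx_inv_diag[1])
    beta_g = coef[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, beta_g / se, 0.0)
    pvals = 2.0 * stats.t.sf(np.abs(tstat), dof)
    constant = bulk.std(axis=0) == 0
    if constant.any():
        logger.info("%d constant CpG columns set to p = 1", int(constant.sum()))
        pvals[constant] = 1.0
    fdr = bh_fdr(pvals)
    if cpg_ids is None:
        cpg_ids = np.array([f"cpg{i:07d}" for i in range(n_cpgs)], dtype=object)
    table = pd.DataFrame(
        {"cpg_id": cpg_ids, "coef": beta_g, "p_value": pvals, "fdr": fdr}
    )
    dmps = set(cpg_ids[fdr < fdr_threshold])
    return dmps, table


def largest_remainder_counts(n_total: int, allocation: dict[str, float]) -> dict[str, int]:
    """Integer apportionment of ``n_total`` by the largest-remainder rule.

    Quotas ``fraction * n_total`` are floored and the leftover units go to
    the categories with the largest fractional remainders (ties broken by
    the fixed category order NEU, MG, OLIG, AST, background).
    """
    order = [c for c in DMP_CATEGORIES if c in allocation]
    quotas = {c: allocation[c] * n_total for c in order}
    counts = {c: int(np.floor(quotas[c])) for c in order}
    leftover = n_total - sum(counts.values())
    remainders = sorted(
        order, key=lambda c: (-(quotas[c] - counts[c]), order.index(c))
    )
    for c in remainders[:leftover]:
        counts[c] += 1
    return counts


def inject_dmps(
    dataset: PseudoBulkDataset,
    n_dmps: int,
    allocation: dict[str, float] | None = None,
    effect_delta: float = 0.2,
    rng: np.random.Generator | None = None,
    designate_only: bool = False,
) -> PseudoBulkDataset:
    """Designate ground-truth DMPs and shift their disease-group bulk betas.

    CpGs are drawn without replacement within each category per the
    allocation (largest-remainder apportionment). Unless ``designate_only``
    is set, disease-group bulk values at designated CpGs are shifted by
    ``effect_delta`` and clamped to [0, 1]. The input dataset is not
    modified; a copy with ``designated_dmps`` recorded is returned.
    """
    if allocation is None:
        allocation = SimulationConfig().dmp_allocation
    if rng is None:
        rng = np.random.default_rng()
    counts = largest_remainder_counts(n_dmps, allocation)
    chosen: list[int] = []
    for cat, k in counts.items():
        if k == 0:
            continue
        pool = np.flatnonzero(dataset.specs.category == cat)
        if k > len(pool):
            raise SimulationError(
                f"category {cat!r} holds {len(pool)} CpGs; cannot designate {k}"
            )
        chosen.extend(rng.choice(pool, size=k, replace=False).tolist())
    chosen_idx = np.array(sorted(chosen), dtype=int)
    bulk = dataset.bulk.copy()
    if not designate_only and len(chosen_idx):
        disease = dataset.group == "disease"
        sub = bulk[np.ix_(disease, chosen_idx)]
        bulk[np.ix_(disease, chosen_idx)] = np.clip(sub + effect_delta, 0.0, 1.0)
    return replace(
        dataset,
        bulk=bulk,
        designated_dmps=set(dataset.cpg_ids[chosen_idx]),
    )


# ---------------------------------------------------------------------------
# dataset assembly and the two experiments
# ---------------------------------------------------------------------------

def generate_pseudobulk(
    config: SimulationConfig,
    rng: np.random.Generator,
    specs: CpGSimSpecs | None = None,
) -> PseudoBulkDataset:
    """Control + disease pseudo-bulk cohorts from one set of CpG specs.

    The generating distributions are identical in both groups; only the
    Dirichlet mixing weights differ (``alpha_control`` vs
    ``alpha_disease``), so composition is the sole group difference.
    """
    if specs is None:
        specs = simulate_cpg_specs(config, rng)
    n = config.n_per_group
    group = np.array(["control"] * n + ["disease"] * n, dtype=object)
    weights = np.vstack(
        [
            draw_weights(n, config.alpha_control, rng),
            draw_weights(n, config.alpha_disease, rng),
        ]
    )
    profiles = sample_cell_profiles(specs, 2 * n, rng)
    bulk = mix_pseudobulk(profiles, weights)
    return PseudoBulkDataset(
        bulk=bulk, cpg_ids=specs.cpg_ids, group=group,
        true_weights=weights, specs=specs,
    )


def _ora_against_sets(
    dmps: set[str], specs: CpGSimSpecs, fdr_threshold: float
) -> list[dict]:
    """ORA of a DMP list against the simulated set definitions.

    An empty DMP list is a valid no-enrichment outcome (OR 0, p 1), not an
    error.
    """
    background = set(specs.cpg_ids)
    rows = []
    pvals = []
    for cell in CELL_TYPES:
        panel_set = specs.set_cpgs(cell)
        if dmps:
            table = build_contingency(dmps, background, panel_set)
            reported, flag, _ = odds_ratio_ha(table)
            p = enrichment_p(table)
            overlap = table.a
        else:
            reported, flag, p, overlap = 0.0, True, 1.0, 0
        rows.append(
            {
                "cell_type": cell, "overlap_n": overlap, "set_size": len(panel_set),
                "input_size": len(dmps), "odds_ratio": reported,
                "p_value": p, "zero_overlap": flag,
            }
        )
        pvals.append(p)
    for row, q in zip(rows, bh_fdr(pvals)):
        row["fdr"] = float(q)
        row["significant"] = bool(q < fdr_threshold)
    return rows


def run_composition_shift_experiment(
    config: SimulationConfig, seed: int | None = None
) -> pd.DataFrame:
    """Composition-confounding sweep: noisy correction vs no correction.

    Per iteration, a fresh pseudo-bulk cohort pair is generated with
    shifted disease composition; DMPs are called once uncorrected and once
    corrected with weights perturbed at each noise SD, and each DMP list is
    scored by ORA against the simulated sets. Returns a tidy per-run frame
    with columns ``iteration, noise_sd, corrected, mean_rmse, n_dmps,
    cell_type, odds_ratio, p_value, fdr, significant``; summarize with
    :func:`summarize_noise_sweep`.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    records = []
    for it in range(config.n_iterations):
        ds = generate_pseudobulk(config, rng)
        dmps_unc, _ = call_dmps(
            ds.bulk, ds.group, None, config.fdr_threshold, ds.cpg_ids
        )
        for row in _ora_against_sets(dmps_unc, ds.specs, config.fdr_threshold):
            records.append(
                {
                    "iteration": it, "noise_sd": np.nan, "corrected": False,
                    "mean_rmse": np.nan, "n_dmps": len(dmps_unc), **row,
                }
            )
        for noise_sd in config.noise_sds:
            perturbed, rmse = perturb_weights(
                ds.true_weights, noise_sd, rng, config.noise_mode
            )
            dmps_cor, _ = call_dmps(
                ds.bulk, ds.group, perturbed, config.fdr_threshold, ds.cpg_ids
            )
            for row in _ora_against_sets(dmps_cor, ds.specs, config.fdr_threshold):
                records.append(
                    {
                        "iteration": it, "noise_sd": noise_sd, "corrected": True,
                        "mean_rmse": rmse, "n_dmps": len(dmps_cor), **row,
                    }
                )
    return pd.DataFrame(records)


def summarize_noise_sweep(results: pd.DataFrame) -> pd.DataFrame:
    """Median OR / p per (noise_sd, corrected, cell_type) with IQR and RMSE."""
    def iqr(x):
        return float(np.subtract(*np.percentile(x, [75, 25])))

    grouped = results.groupby(["corrected", "noise_sd", "cell_type"], dropna=False)
    out = grouped.agg(
        median_or=("odds_ratio", "median"),
        iqr_or=("odds_ratio", iqr),
        median_p=("p_value", "median"),
        median_fdr=("fdr", "median"),
        mean_rmse=("mean_rmse", "mean"),
        frac_significant=("significant", "mean"),
    ).reset_index()
    return out


def run_input_size_experiment(
    config: SimulationConfig, seed: int | None = None
) -> pd.DataFrame:
    """DMP-injection sweep over input sizes, corrected analysis only.

    Both groups draw weights from ``alpha_control`` (no composition
    shift). Per iteration one base cohort is generated; per DMP count, the
    allocation is injected, DMPs are called with the true weights as
    covariates, and the ORA is run. Returns a tidy per-run frame.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    balanced = replace(config, alpha_disease=tuple(config.alpha_control))
    records = []
    for it in range(config.n_iterations):
        ds = generate_pseudobulk(balanced, rng)
        for n_dmps in config.dmp_counts:
            injected = inject_dmps(
                ds, n_dmps, config.dmp_allocation, config.effect_delta, rng
            )
            dmps, _ = call_dmps(
                injected.bulk, injected.group, injected.true_weights,
                config.fdr_threshold, injected.cpg_ids,
            )
            for row in _ora_against_sets(dmps, ds.specs, config.fdr_threshold):
                records.append(
                    {
                        "iteration": it, "n_dmps_injected": n_dmps,
                        "n_dmps_called": len(dmps), **row,
                    }
                )
    return pd.DataFrame(records)


def summarize_input_size(results: pd.DataFrame) -> pd.DataFrame:
    """Median OR / FDR per (injected count, cell type) over iterations."""
    def iqr(x):
        return float(np.subtract(*np.percentile(x, [75, 25])))

    grouped = results.groupby(["n_dmps_injected", "cell_type"])
    return grouped.agg(
        median_or=("odds_ratio", "median"),
        iqr_or=("odds_ratio", iqr),
        median_p=("p_value", "median"),
        median_fdr=("fdr", "median"),
        frac_significant=("significant", "mean"),
    ).reset_index()
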