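"""Deterministic synthetic data: purified-cell cohorts and probe annotations.

These generators let the whole workflow — panel construction, enrichment,
matched permutations — run end-to-end without any external download. They
emulate the structure of the real reference resource (two cohorts of
FANS-sorted nuclei, four cell types per donor, aged donors, donor random
effects) with planted ground truth so that classifier recovery can be
scored:

* *high-specific* CpGs: intermediate mean (0.2-0.8) in one target cell
  type, extreme (<= 0.05 or >= 0.95) in the rest — clear of the 0.1/0.9
  thresholds so recovery is not knife-edge;
* *medium-multi* CpGs: intermediate in two cell types, extreme in two;
* *low-only* CpGs: intermediate in all four cell types with the target
  mean well separated from the (equal) others, so only the mixed-model
  contrast route can annotate them;
* *all-hypo* / *all-hyper* CpGs: extreme in every cell type — ineligible
  for any panel;
* *background* CpGs: a common intermediate mean in all four cell types.

A separate borderline generator places medians exactly on the 0.1/0.9
boundaries to exercise the strict-inequality tie behavior.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panels import CELL_TYPES
from .simulate import _truncnorm_01

COHORTS = ("A", "B")

DEFAULT_CATEGORY_PROPORTIONS = {
    "high": 0.10,       # split evenly over the four target cell types
    "medium": 0.08,     # intermediate in two cell types
    "low_only": 0.08,
    "all_hypo": 0.05,
    "all_hyper": 0.05,  # remainder is background
}

DEFAULT_ANNOTATION_FREQS = {
    "probe_design": {"I": 0.2, "II": 0.8},
    "island_context": {"Island": 0.3, "Shore": 0.25, "Shelf": 0.1, "OpenSea": 0.35},
    "gene_context": {"TSS": 0.3, "Body": 0.45, "Intergenic": 0.25},
}


@dataclass
class PlantedTruth:
    """Per-CpG generating parameters and intended panel membership."""

    cpg_ids: np.ndarray
    category: np.ndarray          # e.g. 'high:NEU', 'medium:NEU+MG', 'background'
    mu: np.ndarray                # (n_cpgs, 4) per-cell-type means
    within_sd: float = 0.03
    donor_sd: float = 0.02
    expected: dict = field(default_factory=dict)  # level -> cell -> set of CpGs

    def expected_sets(self, level: str) -> dict[str, set[str]]:
        return {c: set(self.expected.get(level, {}).get(c, set())) for c in CELL_TYPES}


def make_planted_truth(
    n_cpgs: int,
    rng: np.random.Generator,
    proportions: dict | None = None,
    within_sd: float = 0.03,
    donor_sd: float = 0.02,
) -> PlantedTruth:
    """Assign categories and generating means for ``n_cpgs`` synthetic CpGs."""
    props = dict(DEFAULT_CATEGORY_PROPORTIONS if proportions is None else proportions)
    counts = {k: int(round(v * n_cpgs)) for k, v in props.items()}
    if sum(counts.values()) > n_cpgs:
        raise ValueError("category proportions exceed 1")
    cpg_ids = np.array([f"cg{i:07d}" for i in range(n_cpgs)], dtype=object)
    category = np.full(n_cpgs, "background", dtype=object)
    mu = np.empty((n_cpgs, 4))
    expected: dict = {"high": {c: set() for c in CELL_TYPES},
                      "medium": {c: set() for c in CELL_TYPES},
                      "low": {c: set() for c in CELL_TYPES}}
    pos = 0

    def take(k):
        nonlocal pos
        sl = slice(pos, pos + k)
        pos += k
        return np.arange(n_cpgs)[sl]

    # high-specific: round-robin over target cell types
    idx = take(counts.get("high", 0))
    for n_th, i in enumerate(idx):
        j = n_th % 4
        target = CELL_TYPES[j]
        category[i] = f"high:{target}"
        for k in range(4):
            if k == j:
                mu[i, k] = rng.uniform(0.2, 0.8)
            else:
                mu[i, k] = rng.uniform(0.01, 0.05) if rng.random() < 0.5 else rng.uniform(0.95, 0.99)
        for level in ("high", "medium", "low"):
            expected[level][target].add(cpg_ids[i])

    # medium-multi: intermediate in a pair of cell types, extreme elsewhere
    idx = take(counts.get("medium", 0))
    pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
    for n_th, i in enumerate(idx):
        ja, jb = pairs[n_th % len(pairs)]
        category[i] = f"medium:{CELL_TYPES[ja]}+{CELL_TYPES[jb]}"
        for k in range(4):
            if k in (ja, jb):
                mu[i, k] = rng.uniform(0.2, 0.8)
            else:
                mu[i, k] = rng.uniform(0.01, 0.05) if rng.random() < 0.5 else rng.uniform(0.95, 0.99)
        for j in (ja, jb):
            expected["medium"][CELL_TYPES[j]].add(cpg_ids[i])
            expected["low"][CELL_TYPES[j]].add(cpg_ids[i])

    # low-only: all four intermediate; the target well separated, the other
    # three equal, so only the contrast criterion can single out the target
    idx = take(counts.get("low_only", 0))
    for n_th, i in enumerate(idx):
        j = n_th % 4
        category[i] = f"low:{CELL_TYPES[j]}"
        others = rng.uniform(0.35, 0.45)
        mu[i, :] = others
        mu[i, j] = others + 0.3
        expected["low"][CELL_TYPES[j]].add(cpg_ids[i])

    idx = take(counts.get("all_hypo", 0))
    mu[idx, :] = rng.uniform(0.01, 0.05, size=(len(idx), 4))
    category[idx] = "all_hypo"
    idx = take(counts.get("all_hyper", 0))
    mu[idx, :] = rng.uniform(0.95, 0.99, size=(len(idx), 4))
    category[idx] = "all_hyper"

    # background: one common intermediate mean per CpG across cell types
    rest = np.arange(n_cpgs)[pos:]
    mu[rest, :] = rng.uniform(0.2, 0.8, size=(len(rest), 1))
    return PlantedTruth(
        cpg_ids=cpg_ids, category=category, mu=mu,
        within_sd=within_sd, donor_sd=donor_sd, expected=expected,
    )


def make_borderline_truth(rng: np.random.Generator) -> PlantedTruth:
    """CpGs whose medians sit exactly on the 0.1 / 0.9 thresholds.

    Generated noise-free (within_sd = 0) so the median equals the planted
    value exactly; under the strict-inequality convention none of these may
    enter any panel via the threshold routes.
    """
    rows = [
        ("edge_low", [0.1, 0.05, 0.95, 0.05]),    # target exactly at 0.1
        ("edge_high", [0.9, 0.05, 0.95, 0.05]),   # target exactly at 0.9
        ("edge_gap", [0.15, 0.05, 0.95, 0.95]),   # gap exactly 0.10 -> passes >=
    ]
    cpg_ids = np.array([r[0] for r in rows], dtype=object)
    mu = np.array([r[1] for r in rows])
    return PlantedTruth(
        cpg_ids=cpg_ids,
        category=np.array(["borderline"] * len(rows), dtype=object),
        mu=mu, within_sd=0.0, donor_sd=0.0,
    )


def synth_purified_cohorts(
    n_donors: int,
    truth: PlantedTruth,
    seed: int | None = None,
) -> list[tuple[pd.DataFrame, pd.DataFrame]]:
    """Two synthetic purified-cell cohorts with the planted structure.

    Each cohort holds one sample per (donor, cell type): ages ~ N(82, 9),
    balanced sexes, beta = truncated-normal(mu + donor effect, within SD).
    The donor effect is a per-(donor, CpG) random intercept shared across
    that donor's four samples. Returns ``[(betas, metadata), (betas,
    metadata)]`` in the TSV-ready layouts (CpG x sample; metadata rows).
    """
    if n_donors < 4:
        raise ValueError("need at least 4 donors per cohort")
    rng = np.random.default_rng(seed)
    n_cpgs = len(truth.cpg_ids)
    out = []
    for cohort in COHORTS:
        donor_ids = [f"{cohort}D{d:02d}" for d in range(n_donors)]
        ages = np.clip(rng.normal(82, 9, size=n_donors), 60, 105).round(1)
        sexes = np.array(["F", "M"] * ((n_donors + 1) // 2))[:n_donors]
        donor_effect = rng.normal(0.0, truth.donor_sd, size=(n_donors, n_cpgs))
        columns = {}
        meta_rows = []
        for d, donor in enumerate(donor_ids):
            for j, cell in enumerate(CELL_TYPES):
                sample_id = f"{cohort}_{donor}_{cell}"
                loc = np.clip(truth.mu[:, j] + donor_effect[d], 0.0, 1.0)
                columns[sample_id] = _truncnorm_01(
                    loc, np.full(n_cpgs, truth.within_sd), rng
                )
                meta_rows.append(
                    (sample_id, donor, cell, float(ages[d]), sexes[d], cohort)
                )
        betas = pd.DataFrame(columns, index=pd.Index(truth.cpg_ids, name="cpg_id"))
        meta = pd.DataFrame(
            meta_rows,
            columns=["sample_id", "donor_id", "cell_type", "age", "sex", "cohort"],
        )
        out.append((betas, meta))
    return out


def synth_probe_annotation(
    cpg_ids,
    seed: int | None = None,
    freqs: dict | None = None,
) -> pd.DataFrame:
    """Random probe annotations with configurable marginal frequencies."""
    cpg_ids = list(cpg_ids)
    if not cpg_ids:
        raise ValueError("cpg_ids must be non-empty")
    if freqs is None:
        freqs = DEFAULT_ANNOTATION_FREQS
    rng = np.random.default_rng(seed)
    data = {"cpg_id": cpg_ids}
    for factor, table in freqs.items():
        levels = list(table)
        probs = np.array([table[k] for k in levels], float)
        probs = probs / probs.sum()
        data[factor] = rng.choice(levels, size=len(cpg_ids), p=probs)
    return pd.DataFrame(data)
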