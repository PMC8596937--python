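"""Synthetic reference methylomes, matched cohorts and ddPCR-style readouts.

The generator is the study substrate for the whole pipeline. It emulates:

* a sorted-leukocyte reference methylome with planted subtype-specific
  unmethylated sites and opposing neutrophil-/pan-lymphocyte-methylated
  sites over a shared background;
* a 1:1 age-matched case-control blood cohort in which each sample's betas
  are a noisy convex mixture of the reference profiles, with latent
  proportions drawn from group-specific Dirichlet distributions. The default
  group means are calibrated to the published whole-blood shifts: neutrophils
  0.49 (cases) vs 0.45 (controls), pan-lymphocyte totals 0.36 vs 0.403, with
  NK cells carrying the largest relative drop;
* a prospective arm of per-sample NK "unmethylation" ratios as produced by a
  MethyLight droplet digital PCR assay, age-matched at +/- 5 years.

The generator models measurement error as additive Gaussian noise on beta
with clipping, and does not attempt array artefacts (probe-type bias,
batches) or biological covariate-proportion dependence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .marker_panel import CELL_TYPES, ReferenceMethylome

#: six mixed cell types (Treg enters betas as a fixed fraction of TCD4)
MIX_TYPES = ("Neu", "NK", "TCD4", "TCD8", "B", "Mono")

DEFAULT_CONTROL_PROPS = {
    "Neu": 0.45, "NK": 0.063, "TCD4": 0.17, "TCD8": 0.10, "B": 0.07, "Mono": 0.147,
}
DEFAULT_CASE_PROPS = {
    "Neu": 0.49, "NK": 0.043, "TCD4": 0.155, "TCD8": 0.095, "B": 0.067, "Mono": 0.15,
}


@dataclass
class CohortConfig:
    """Study conditions for the synthetic matched cohort.

    Group mean proportions must each sum to one. ``dirichlet_mass`` is the
    total concentration (higher = less between-subject spread);
    ``noise_sd`` the beta measurement noise; ages are drawn from a truncated
    normal and matched within ``age_tolerance`` years.
    """

    n_pairs: int = 231
    seed: int = 0
    control_props: dict = field(default_factory=lambda: dict(DEFAULT_CONTROL_PROPS))
    case_props: dict = field(default_factory=lambda: dict(DEFAULT_CASE_PROPS))
    dirichlet_mass: float = 60.0
    noise_sd: float = 0.02
    age_mean: float = 55.0
    age_sd: float = 8.0
    age_min: float = 30.0
    age_max: float = 80.0
    age_tolerance: float = 1.0
    treg_frac_of_tcd4: float = 0.1

    def __post_init__(self) -> None:
        for name, props in (("control", self.control_props), ("case", self.case_props)):
            vec = np.array([props[c] for c in MIX_TYPES], dtype=float)
            if (vec < 0).any():
                raise ValueError(f"{name} mean proportions must be nonnegative")
            if not np.isclose(vec.sum(), 1.0, atol=1e-8):
                raise ValueError(f"{name} mean proportions must sum to 1 (got {vec.sum()})")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")


def simulate_reference(
    n_probes: int = 300,
    cell_types=CELL_TYPES,
    markers_per_type: int = 3,
    n_opposing: int = 3,
    seed: int = 0,
) -> ReferenceMethylome:
    """Reference methylome with planted subtype-specific markers.

    Per subtype, ``markers_per_type`` target-unmethylated probes (target beta
    ~ U(0.02, 0.1), others ~ U(0.85, 0.98)); ``n_opposing`` probes methylated
    in neutrophils only and in pan-lymphocytes only (same beta ranges);
    remaining probes share one background beta ~ U(0.2, 0.8) across types.
    Planted margins are >= 0.75 by construction, so default-threshold
    selection recovers exactly the planted sets.
    """
    cell_types = list(cell_types)
    rng = np.random.default_rng(seed)
    n_planted = markers_per_type * len(cell_types) + 2 * n_opposing
    if n_probes < n_planted:
        raise ValueError(f"n_probes must be >= {n_planted} to hold the planted markers")
    probe_ids = [f"cg{i:08d}" for i in range(n_probes)]
    betas = pd.DataFrame(
        np.tile(rng.uniform(0.2, 0.8, size=(n_probes, 1)), (1, len(cell_types))),
        index=pd.Index(probe_ids, name="probe_id"),
        columns=cell_types,
    )
    row = 0
    for ct in cell_types:
        for _ in range(markers_per_type):
            betas.iloc[row] = rng.uniform(0.85, 0.98, size=len(cell_types))
            betas.iloc[row, betas.columns.get_loc(ct)] = rng.uniform(0.02, 0.1)
            row += 1
    lymph = ["NK", "TCD4", "TCD8", "B"]
    low_in = {"neu": [c for c in cell_types if c != "Neu"], "lym": ["Neu", "Mono"]}
    for _ in range(n_opposing):  # methylated in neutrophils only
        betas.iloc[row] = rng.uniform(0.02, 0.1, size=len(cell_types))
        betas.iloc[row, betas.columns.get_loc("Neu")] = rng.uniform(0.85, 0.98)
        row += 1
    for _ in range(n_opposing):  # methylated in the pan-lymphocyte group
        betas.iloc[row] = rng.uniform(0.02, 0.1, size=len(cell_types))
        for c in lymph + (["Treg"] if "Treg" in cell_types else []):
            betas.iloc[row, betas.columns.get_loc(c)] = rng.uniform(0.85, 0.98)
        row += 1
    return ReferenceMethylome(betas)


def _truncated_normal(rng, mean, sd, lo, hi, size):
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.normal(mean, sd, size=size)
        ok = draw[(draw >= lo) & (draw <= hi)]
        take = min(len(ok), size - filled)
        out[filled : filled + take] = ok[:take]
        filled += take
    return out


def _mixture_betas(ref: ReferenceMethylome, weights: pd.DataFrame,
                   treg_frac: float, noise_sd: float, rng) -> pd.DataFrame:
    """Observed betas = reference @ effective weights + Gaussian noise, clipped."""
    cols = list(ref.betas.columns)
    eff = pd.DataFrame(0.0, index=weights.index, columns=cols)
    for c in MIX_TYPES:
        eff[c] = weights[c]
    if "Treg" in cols:
        eff["Treg"] = treg_frac * weights["TCD4"]
        eff["TCD4"] = (1 - treg_frac) * weights["TCD4"]
    mixed = eff.to_numpy() @ ref.betas[cols].to_numpy().T
    if noise_sd > 0:
        mixed = mixed + rng.normal(0.0, noise_sd, size=mixed.shape)
    mixed = np.clip(mixed, 0.0, 1.0)
    return pd.DataFrame(mixed, index=weights.index, columns=ref.betas.index)


def simulate_cohort(
    ref: ReferenceMethylome, config: CohortConfig
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Matched case-control cohort as noisy mixtures of the reference.

    Returns (betas, sample_sheet, true_proportions): betas is samples x
    probes; the sample sheet carries pair_id, is_case, age and epidemiologic
    covariates (bmi, postmenopausal, ever_parous, current_smoker), all drawn
    independently of case status; true_proportions holds the latent six-type
    simplex weights per sample.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_pairs
    ctrl_mean = np.array([config.control_props[c] for c in MIX_TYPES])
    case_mean = np.array([config.case_props[c] for c in MIX_TYPES])

    ctrl_age = _truncated_normal(
        rng, config.age_mean, config.age_sd, config.age_min, config.age_max, n
    )
    case_age = np.clip(
        ctrl_age + rng.uniform(-config.age_tolerance, config.age_tolerance, n),
        config.age_min,
        config.age_max,
    )
    w_ctrl = rng.dirichlet(config.dirichlet_mass * ctrl_mean, size=n)
    w_case = rng.dirichlet(config.dirichlet_mass * case_mean, size=n)

    rows, weights = [], []
    for i in range(n):
        for status, age, w in (
            (True, case_age[i], w_case[i]),
            (False, ctrl_age[i], w_ctrl[i]),
        ):
            sid = f"P{i:04d}_{'case' if status else 'ctrl'}"
            rows.append(
                {
                    "sample_id": sid,
                    "pair_id": f"P{i:04d}",
                    "is_case": status,
                    "age": float(age),
                    "bmi": float(np.clip(rng.normal(26.0, 4.0), 16, 50)),
                    "postmenopausal": bool(rng.random() < (age > 51) * 0.85 + 0.05),
                    "ever_parous": bool(rng.random() < 0.8),
                    "current_smoker": bool(rng.random() < 0.2),
                }
            )
            weights.append(w)
    sheet = pd.DataFrame(rows).set_index("sample_id")
    truth = pd.DataFrame(
        np.asarray(weights), index=sheet.index, columns=list(MIX_TYPES)
    )
    betas = _mixture_betas(ref, truth, config.treg_frac_of_tcd4, config.noise_sd, rng)
    return betas, sheet, truth


def simulate_prospective_ddpcr(
    config: CohortConfig | None = None,
    n_pairs: int = 146,
    assay_cv: float = 0.05,
    seed: int | None = None,
) -> pd.DataFrame:
    """Prospective-arm NK unmethylation ratios from a single-locus assay.

    Each sample's readout is its latent NK proportion scaled by a
    multiplicative assay efficiency ~ N(1, ``assay_cv``), clipped to (0, 1).
    Pairs are age-matched at +/- 5 years. Returns one row per sample with
    pair_id, is_case, age and ``nk_unmeth``.
    """
    config = config or CohortConfig(age_tolerance=5.0)
    rng = np.random.default_rng(config.seed if seed is None else seed)
    ctrl_age = _truncated_normal(
        rng, config.age_mean, config.age_sd, config.age_min, config.age_max, n_pairs
    )
    case_age = np.clip(
        ctrl_age + rng.uniform(-config.age_tolerance, config.age_tolerance, n_pairs),
        config.age_min,
        config.age_max,
    )
    w_ctrl = rng.dirichlet(
        config.dirichlet_mass * np.array([config.control_props[c] for c in MIX_TYPES]),
        size=n_pairs,
    )[:, MIX_TYPES.index("NK")]
    w_case = rng.dirichlet(
        config.dirichlet_mass * np.array([config.case_props[c] for c in MIX_TYPES]),
        size=n_pairs,
    )[:, MIX_TYPES.index("NK")]
    eff = rng.normal(1.0, assay_cv, size=(n_pairs, 2))
    eps = 1e-9
    rows = []
    for i in range(n_pairs):
        for status, age, w, e in (
            (True, case_age[i], w_case[i], eff[i, 0]),
            (False, ctrl_age[i], w_ctrl[i], eff[i, 1]),
        ):
            rows.append(
                {
                    "sample_id": f"G{i:04d}_{'case' if status else 'ctrl'}",
                    "pair_id": f"G{i:04d}",
                    "is_case": status,
                    "age": float(age),
                    "nk_unmeth": float(np.clip(w * e, eps, 1 - eps)),
                }
            )
    return pd.DataFrame(rows).set_index("sample_id")
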