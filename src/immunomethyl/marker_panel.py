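"""Selection of leukocyte-subtype-specific CpG markers from a reference methylome.

A reference methylome gives mean beta values (methylation fractions in [0,1])
for purified leukocyte subtypes. Because methylation at a subtype-specific
locus dilutes linearly with cell mixing, a CpG that is unmethylated in exactly
one subtype and methylated in all others (an ISUS: immune cell-specific
unmethylated site) acts as a proxy for that subtype's abundance in whole
blood. This module picks such sites, plus the opposing neutrophil-methylated
and pan-lymphocyte-methylated sets used for methylation-derived
neutrophil-to-lymphocyte ratios (mdNLR).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

#: canonical subtype labels: B cells, monocytes, natural killer cells,
#: neutrophils, CD4+ T, CD8+ T, regulatory T cells
CELL_TYPES = ("B", "Mono", "NK", "Neu", "TCD4", "TCD8", "Treg")

#: the lymphoid compartment entering the pan-lymphocyte group
PAN_LYMPHOCYTE = ("NK", "TCD4", "TCD8", "B")

TARGET_UNMETHYLATED = "target-unmethylated"
TARGET_METHYLATED = "target-methylated"


@dataclass
class ReferenceMethylome:
    """Probes x cell-type mean beta matrix.

    Parameters
    ----------
    betas
        DataFrame indexed by CpG probe id (Illumina-style ``cg...``) with one
        column per cell type; values in [0, 1].
    coords
        Optional DataFrame (same index) with ``chrom`` and 1-based ``pos``
        columns (GRCh37).
    """

    betas: pd.DataFrame
    coords: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.betas.index.has_duplicates:
            dup = self.betas.index[self.betas.index.duplicated()][0]
            raise ValueError(f"duplicate probe_id in reference: {dup!r}")
        vals = self.betas.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("reference beta values must lie in [0, 1]")

    @property
    def cell_types(self) -> list[str]:
        return list(self.betas.columns)

    @property
    def probe_ids(self) -> pd.Index:
        return self.betas.index

    def complete(self) -> pd.DataFrame:
        """Betas restricted to probes with no missing value (selection substrate)."""
        return self.betas.dropna(axis=0, how="any")


@dataclass(frozen=True)
class MarkerSpec:
    """One selected marker CpG.

    ``margin`` is the specificity score: the gap between the least extreme
    beta on the 'wrong' side and the most extreme on the target side (see
    :func:`specificity_margin`). Negative margins mean no specificity.
    """

    probe_id: str
    target: str
    orientation: str
    margin: float


@dataclass
class MarkerPanel:
    """Named marker sets driving all downstream proxy scoring.

    ``isus`` maps each subtype to its target-unmethylated sites;
    ``neu_methylated`` / ``panlym_methylated`` are the opposing sets whose
    beta ratio defines the mdNLR. ``provenance`` records selection
    parameters and any shortfall warnings.
    """

    isus: dict[str, list[MarkerSpec]] = field(default_factory=dict)
    neu_methylated: list[MarkerSpec] = field(default_factory=list)
    panlym_methylated: list[MarkerSpec] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for subtype, specs in self.isus.items():
            for s in specs:
                if s.probe_id in seen:
                    raise ValueError(
                        f"probe {s.probe_id} assigned to both "
                        f"{seen[s.probe_id]} and {subtype}"
                    )
                seen[s.probe_id] = subtype

    def isus_probes(self, subtype: str) -> list[str]:
        return [s.probe_id for s in self.isus.get(subtype, [])]

    @property
    def neu_probes(self) -> list[str]:
        return [s.probe_id for s in self.neu_methylated]

    @property
    def panlym_probes(self) -> list[str]:
        return [s.probe_id for s in self.panlym_methylated]

    def all_specs(self) -> list[MarkerSpec]:
        out = [s for specs in self.isus.values() for s in specs]
        out += self.neu_methylated + self.panlym_methylated
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "probe_id": s.probe_id,
                "target": s.target,
                "orientation": s.orientation,
                "margin": s.margin,
            }
            for s in self.all_specs()
        ]
        return pd.DataFrame(rows, columns=["probe_id", "target", "orientation", "margin"])

    # ------------------------------------------------------------------ io
    def to_yaml(self, path) -> None:
        doc = {
            "isus": {
                t: [vars(s) for s in specs] for t, specs in self.isus.items()
            },
            "neu_methylated": [vars(s) for s in self.neu_methylated],
            "panlym_methylated": [vars(s) for s in self.panlym_methylated],
            "provenance": self.provenance,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path_or_stream) -> "MarkerPanel":
        if hasattr(path_or_stream, "read"):
            doc = yaml.safe_load(path_or_stream)
        else:
            with open(path_or_stream) as fh:
                doc = yaml.safe_load(fh)
        return cls(
            isus={
                t: [MarkerSpec(**d) for d in specs]
                for t, specs in (doc.get("isus") or {}).items()
            },
            neu_methylated=[MarkerSpec(**d) for d in doc.get("neu_methylated") or []],
            panlym_methylated=[MarkerSpec(**d) for d in doc.get("panlym_methylated") or []],
            provenance=doc.get("provenance") or {},
        )


def specificity_margin(
    betas_for_probe: pd.Series,
    target_set,
    orientation: str = TARGET_UNMETHYLATED,
) -> float:
    """Specificity gap of one probe for a target cell-type set.

    target-unmethylated: ``min(beta over non-targets) - max(beta over targets)``;
    target-methylated: ``min(beta over targets) - max(beta over non-targets)``.
    A large positive margin means a clean binary profile; negative means the
    probe does not separate the groups.
    """
    targets = list(target_set)
    if not targets:
        raise ValueError("empty target set")
    missing = [t for t in targets if t not in betas_for_probe.index]
    if missing:
        raise KeyError(f"cell types {missing} absent from beta vector")
    if betas_for_probe.isna().any():
        bad = betas_for_probe.index[betas_for_probe.isna()][0]
        raise ValueError(
            f"missing beta for cell type {bad!r} (probe {betas_for_probe.name!r})"
        )
    tgt = betas_for_probe.loc[targets]
    non = betas_for_probe.drop(index=targets)
    if non.empty:
        raise ValueError("no non-target cell types to contrast against")
    if orientation == TARGET_UNMETHYLATED:
        return float(non.min() - tgt.max())
    if orientation == TARGET_METHYLATED:
        return float(tgt.min() - non.max())
    raise ValueError(f"unknown orientation {orientation!r}")


def _candidate_table(
    betas: pd.DataFrame, low_thr: float, high_thr: float
) -> pd.DataFrame:
    """Per (probe, subtype) ISUS candidacy and margin, vectorised."""
    vals = betas.to_numpy(dtype=float)
    n_probes, n_types = vals.shape
    rows = []
    for j, subtype in enumerate(betas.columns):
        others = np.delete(vals, j, axis=1)
        ok = (vals[:, j] <= low_thr) & (others.min(axis=1) >= high_thr)
        margin = others.min(axis=1) - vals[:, j]
        for i in np.flatnonzero(ok):
            rows.append((betas.index[i], subtype, float(margin[i])))
    return pd.DataFrame(rows, columns=["probe_id", "target", "margin"])


def select_isus(
    ref: ReferenceMethylome,
    k_per_type: int = 3,
    low_thr: float = 0.3,
    high_thr: float = 0.7,
) -> MarkerPanel:
    """Select per-subtype target-unmethylated sites (ISUS).

    A probe is a candidate for a subtype when its beta in that subtype is
    <= ``low_thr`` and >= ``high_thr`` in every other subtype. Probes eligible
    for several subtypes go to the subtype with the largest margin (ties to
    the lexicographically smallest probe id); the top ``k_per_type`` by margin
    are kept per subtype. Deterministic for fixed input.

    Subtypes with fewer than ``k_per_type`` candidates yield what exists plus
    a warning record in ``provenance['warnings']``.
    """
    if not (0 <= low_thr < high_thr <= 1):
        raise ValueError("need 0 <= low_thr < high_thr <= 1")
    if k_per_type < 1:
        raise ValueError("k_per_type must be >= 1")
    betas = ref.complete().sort_index()
    cand = _candidate_table(betas, low_thr, high_thr)
    warnings: list[str] = []
    isus: dict[str, list[MarkerSpec]] = {t: [] for t in betas.columns}
    if not cand.empty:
        # resolve multi-subtype eligibility: keep the best subtype per probe
        cand = cand.sort_values(
            ["probe_id", "margin", "target"], ascending=[True, False, True]
        ).drop_duplicates("probe_id", keep="first")
        for subtype, grp in cand.groupby("target"):
            grp = grp.sort_values(["margin", "probe_id"], ascending=[False, True])
            isus[subtype] = [
                MarkerSpec(r.probe_id, subtype, TARGET_UNMETHYLATED, r.margin)
                for r in grp.head(k_per_type).itertuples()
            ]
    for subtype in betas.columns:
        n = len(isus[subtype])
        if n < k_per_type:
            warnings.append(
                f"{subtype}: only {n} of {k_per_type} requested ISUS candidates"
            )
    return MarkerPanel(
        isus=isus,
        provenance={
            "k_per_type": k_per_type,
            "low_thr": low_thr,
            "high_thr": high_thr,
            "warnings": warnings,
        },
    )


def select_opposing_markers(
    ref: ReferenceMethylome,
    group_a=("Neu",),
    group_b=PAN_LYMPHOCYTE,
    neutral=("Mono",),
    k: int = 3,
    low_thr: float = 0.3,
    high_thr: float = 0.7,
) -> tuple[list[MarkerSpec], list[MarkerSpec], list[str]]:
    """Select the opposing neutrophil-/pan-lymphocyte-methylated mdNLR sets.

    group-a-methylated sites: beta >= ``high_thr`` in every group-a type and
    <= ``low_thr`` in group-b and neutral types (and vice versa). Types in
    neither group (e.g. Treg) are unconstrained. Returns (a_methylated,
    b_methylated, warnings), each list top-k by margin.
    """
    group_a, group_b, neutral = list(group_a), list(group_b), list(neutral)
    pools = group_a + group_b + neutral
    if len(set(pools)) != len(pools):
        raise ValueError("group_a, group_b and neutral must be disjoint")
    betas = ref.complete().sort_index()
    warnings: list[str] = []

    def pick(meth: list[str], unmeth: list[str], label: str) -> list[MarkerSpec]:
        hi = betas[meth].min(axis=1)
        lo = betas[unmeth].max(axis=1)
        ok = (hi >= high_thr) & (lo <= low_thr)
        margin = (hi - lo)[ok]
        order = margin.to_frame("margin").reset_index(names="probe_id")
        order = order.sort_values(["margin", "probe_id"], ascending=[False, True])
        specs = [
            MarkerSpec(r.probe_id, label, TARGET_METHYLATED, float(r.margin))
            for r in order.head(k).itertuples()
        ]
        if len(specs) < k:
            warnings.append(f"{label}: only {len(specs)} of {k} requested markers")
        return specs

    neu_specs = pick(group_a, group_b + neutral, "neutrophil")
    lym_specs = pick(group_b, group_a + neutral, "pan-lymphocyte")
    return neu_specs, lym_specs, warnings


def build_panel(
    ref: ReferenceMethylome,
    k_per_type: int = 3,
    k_opposing: int = 3,
    low_thr: float = 0.3,
    high_thr: float = 0.7,
) -> MarkerPanel:
    """ISUS plus opposing mdNLR marker sets in one panel."""
    panel = select_isus(ref, k_per_type, low_thr, high_thr)
    neu, lym, warn = select_opposing_markers(
        ref, k=k_opposing, low_thr=low_thr, high_thr=high_thr
    )
    panel.neu_methylated = neu
    panel.panlym_methylated = lym
    panel.provenance["k_opposing"] = k_opposing
    panel.provenance["warnings"].extend(warn)
    return panel


def load_published_panel() -> MarkerPanel:
    """The packaged blood leukocyte marker panel.

    Curated 450K CpGs (GRCh37 coordinates) from published sorted-leukocyte
    methylomes: 21 ISUS (three per subtype) plus three neutrophil-methylated
    and three pan-lymphocyte-methylated mdNLR sites, with group mean betas
    from a TNBC case-control study attached in provenance. Selection margins
    for these probes are not published, so they are stored as NaN.
    """
    src = importlib.resources.files("immunomethyl.data") / "blood_marker_panel.yaml"
    with src.open() as fh:
        return MarkerPanel.from_yaml(fh)
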