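"""Per-sample immune-cell-ratio proxies from beta values at panel CpGs.

Methylation at an ISUS is inversely proportional to the abundance of its
target subtype, so ``1 - beta`` ("unmethylation") is the cell-ratio proxy.
The mdNLR score divides the beta at a neutrophil-methylated CpG by the beta
at a pan-lymphocyte-methylated CpG; with a panel of three sites each this
yields nine mdNLR columns per sample.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .marker_panel import MarkerPanel

EPS = 1e-6


def _require_probes(betas: pd.DataFrame, probes) -> None:
    missing = [p for p in probes if p not in betas.columns]
    if missing:
        raise KeyError(f"probes absent from beta matrix: {missing}")


def logit_transform(beta, eps: float = EPS):
    """ln(b / (1-b)) with b clipped into [eps, 1-eps].

    Vectorised; strictly increasing on the clipped range. Used for the
    analyses run on the logit scale (e.g. ddPCR unmethylation ratios).
    """
    if not (0 < eps < 0.5):
        raise ValueError("eps must lie in (0, 0.5)")
    b = np.clip(np.asarray(beta, dtype=float), eps, 1 - eps)
    out = np.log(b / (1 - b))
    if np.isscalar(beta) or np.ndim(beta) == 0:
        return float(out)
    if isinstance(beta, pd.Series):
        return pd.Series(out, index=beta.index, name=beta.name)
    if isinstance(beta, pd.DataFrame):
        return pd.DataFrame(out, index=beta.index, columns=beta.columns)
    return out


def compute_mdnlr(
    betas: pd.DataFrame, neu_probes, lym_probes, eps: float = EPS
) -> pd.DataFrame:
    """mdNLR scores: beta(neutrophil CpG) / beta(pan-lymphocyte CpG).

    One column per (neutrophil probe, lymphocyte probe) pair, named
    ``<neuProbe>.<lymProbe>``. Samples with a missing input beta get a
    missing score but are retained.
    """
    neu_probes, lym_probes = list(neu_probes), list(lym_probes)
    _require_probes(betas, neu_probes + lym_probes)
    out = {}
    for n in neu_probes:
        num = betas[n].astype(float)
        for l in lym_probes:
            den = betas[l].astype(float).clip(lower=eps)
            out[f"{n}.{l}"] = num / den
    return pd.DataFrame(out, index=betas.index)


def unmethylation_ratio_panel(betas: pd.DataFrame, panel: MarkerPanel) -> pd.DataFrame:
    """Tidy per-sample, per-ISUS proxy table.

    Columns: sample_id, subtype, probe_id, beta, unmeth (= 1 - beta),
    logit_beta. Missing betas propagate as missing scores.
    """
    probes = [p for t in panel.isus for p in panel.isus_probes(t)]
    _require_probes(betas, probes)
    frames = []
    for subtype, specs in panel.isus.items():
        for s in specs:
            b = betas[s.probe_id].astype(float)
            frames.append(
                pd.DataFrame(
                    {
                        "sample_id": betas.index,
                        "subtype": subtype,
                        "probe_id": s.probe_id,
                        "beta": b.to_numpy(),
                        "unmeth": (1.0 - b).to_numpy(),
                        "logit_beta": logit_transform(b).to_numpy(),
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def subtype_unmeth_scores(betas: pd.DataFrame, panel: MarkerPanel) -> pd.DataFrame:
    """Per-sample mean unmethylation over each subtype's ISUS (wide form)."""
    tidy = unmethylation_ratio_panel(betas, panel)
    return tidy.pivot_table(
        index="sample_id", columns="subtype", values="unmeth", aggfunc="mean"
    ).reindex(betas.index)


def nk_neutrophil_ratio(
    betas: pd.DataFrame, nk_probes, neu_probes, eps: float = EPS
) -> pd.DataFrame:
    """NK-to-neutrophil ratio proxies: (1-beta_NK) / (1-beta_Neu) per probe pair.

    Both numerator and denominator are unmethylation proxies, so the score
    rises with the NK ratio and falls with the neutrophil ratio.
    """
    nk_probes, neu_probes = list(nk_probes), list(neu_probes)
    _require_probes(betas, nk_probes + neu_probes)
    out = {}
    for a in nk_probes:
        num = 1.0 - betas[a].astype(float)
        for b in neu_probes:
            den = (1.0 - betas[b].astype(float)).clip(lower=eps)
            out[f"{a}.{b}"] = num / den
    return pd.DataFrame(out, index=betas.index)


def scores_to_tidy(scores: pd.DataFrame) -> pd.DataFrame:
    """Wide sample x score table -> tidy (sample_id, score_name, value)."""
    tidy = scores.reset_index(names="sample_id").melt(
        id_vars="sample_id", var_name="score_name", value_name="value"
    )
    return tidy.sort_values(["score_name", "sample_id"], kind="stable").reset_index(
        drop=True
    )
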