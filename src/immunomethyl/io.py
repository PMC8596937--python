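"""TSV/CSV readers and writers for cohort methylation data, plus provenance.

The analytical entry point is processed beta values, so files are plain
delimited text: a beta matrix has a ``probe_id`` first column and one numeric
column per sample; a sample sheet is one row per sample with pair/case
metadata. All writers prepend a ``#``-comment provenance header (config hash,
seeds, package version) so identical runs produce identical files.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from . import __version__
from .marker_panel import ReferenceMethylome
from .matched_stats import MatchedCohort


def _sep_for(path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_beta_matrix(path) -> pd.DataFrame:
    """Read a probes-as-rows beta table into a samples x probes DataFrame.

    Values must be in [0, 1] or missing (``NA``/empty). Duplicate sample or
    probe ids and non-numeric cells are rejected with the offending cell
    named.
    """
    df = pd.read_csv(path, sep=_sep_for(path), comment="#", dtype=str)
    if df.columns[0] != "probe_id":
        raise ValueError(f"{path}: first column must be 'probe_id', got {df.columns[0]!r}")
    df = df.set_index("probe_id")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate probe id {dup!r}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise ValueError(f"{path}: duplicate sample id {dup!r}")
    out = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() & df[col].notna() & (df[col].str.strip() != "") \
            & (df[col].str.upper() != "NA")
        if bad.any():
            probe = df.index[bad][0]
            raise ValueError(
                f"{path}: non-numeric value {df.loc[probe, col]!r} "
                f"at probe {probe!r}, sample {col!r}"
            )
        out[col] = parsed
    vals = out.to_numpy()
    oob = (vals < 0) | (vals > 1)
    if oob.any():
        i, j = map(int, next(zip(*oob.nonzero())))
        raise ValueError(
            f"{path}: beta {vals[i, j]} out of [0,1] at probe "
            f"{out.index[i]!r}, sample {out.columns[j]!r}"
        )
    return out.T  # samples x probes


def write_beta_matrix(betas: pd.DataFrame, path, provenance: dict | None = None) -> None:
    """Write a samples x probes matrix as probes-as-rows TSV/CSV."""
    _write_with_header(betas.T.rename_axis("probe_id").reset_index(), path, provenance)


def read_reference(path) -> ReferenceMethylome:
    """Reference methylome TSV/CSV: probe_id, optional chrom/pos, cell types."""
    df = pd.read_csv(path, sep=_sep_for(path), comment="#")
    if df.columns[0] != "probe_id":
        raise ValueError(f"{path}: first column must be 'probe_id'")
    df = df.set_index("probe_id")
    coord_cols = [c for c in ("chrom", "pos") if c in df.columns]
    coords = df[coord_cols] if coord_cols else None
    betas = df.drop(columns=coord_cols).astype(float)
    return ReferenceMethylome(betas, coords)


def write_reference(ref: ReferenceMethylome, path, provenance: dict | None = None) -> None:
    df = ref.betas.copy()
    if ref.coords is not None:
        df = pd.concat([ref.coords, df], axis=1)
    _write_with_header(df.rename_axis("probe_id").reset_index(), path, provenance)


def read_sample_sheet(
    path, age_tolerance: float = 1.0, policy: str = "strict"
) -> MatchedCohort:
    """Read and validate a matched-pair sample sheet.

    Requires columns sample_id, pair_id, is_case (0/1 or true/false) and age.
    ``policy='strict'`` raises on structural violations (two cases in a pair,
    unmatched samples, age gap beyond tolerance), naming the rows involved;
    ``policy='warn'`` keeps only the valid pairs and records the dropped ones
    in ``cohort.samples.attrs['warnings']``.
    """
    df = pd.read_csv(path, sep=_sep_for(path), comment="#")
    required = {"sample_id", "pair_id", "is_case"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: sample sheet missing columns {sorted(missing)}")
    df["is_case"] = (
        df["is_case"].astype(str).str.strip().str.lower().map(
            {"1": True, "true": True, "yes": True, "0": False, "false": False, "no": False}
        )
    )
    if df["is_case"].isna().any():
        row = int(df.index[df["is_case"].isna()][0]) + 2  # 1-based + header
        raise ValueError(f"{path}: unparseable is_case value at row {row}")
    df = df.set_index("sample_id")
    try:
        return MatchedCohort(df, age_tolerance)
    except ValueError as err:
        if policy == "strict":
            raise ValueError(f"{path}: {err}") from err
        # warn policy: keep valid pairs only
        bad_pairs = set()
        for pid, grp in df.groupby("pair_id"):
            ok = len(grp) == 2 and int(grp["is_case"].sum()) == 1
            if ok and "age" in grp.columns:
                ok = abs(float(grp["age"].iloc[0]) - float(grp["age"].iloc[1])) \
                    <= age_tolerance + 1e-9
            if not ok:
                bad_pairs.add(pid)
        kept = df[~df["pair_id"].isin(bad_pairs)]
        cohort = MatchedCohort(kept, age_tolerance)
        cohort.samples.attrs["warnings"] = [
            f"dropped invalid pair {p!r}" for p in sorted(map(str, bad_pairs))
        ]
        return cohort


def provenance_header(config: dict | None = None, seeds: dict | None = None) -> list[str]:
    payload = json.dumps({"config": config or {}, "seeds": seeds or {}}, sort_keys=True,
                         default=str)
    digest = hashlib.sha256(payload.encode()).hexdigest()[:16]
    lines = [f"# immunomethyl {__version__}", f"# config_hash: {digest}"]
    for k, v in (seeds or {}).items():
        lines.append(f"# seed.{k}: {v}")
    return lines


def _write_with_header(df: pd.DataFrame, path, provenance: dict | None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = provenance_header(**(provenance or {}))
    with open(path, "w") as fh:
        fh.write("\n".join(header) + "\n")
        df.to_csv(fh, sep=_sep_for(path), index=False)


def write_results(results: pd.DataFrame, path, provenance: dict | None = None) -> None:
    """Deterministic results writer: sorted columns after the index column."""
    df = results.reset_index()
    ordered = [df.columns[0], *sorted(df.columns[1:])]
    _write_with_header(df[ordered], path, provenance)


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep=_sep_for(path), comment="#")
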