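"""PSM score tables and PEP result tables.

The exchange format is a plain UTF-8 TSV with a header.  A PSM table names
four columns (``psm_id``, ``score``, ``label``, ``in_group``); scores are
dimensionless with higher = more confident (E-value-like scores must be
negated/transformed upstream).  ``label`` marks each record as a match to
the target or the decoy database; ``in_group`` marks membership in the
group of interest G (its complement is Q).

A PEP result table carries one row per target PSM with its posterior error
probability and the integrated FDR (running mean of PEP down the score
ranking), written at full float precision so that write -> read is the
identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np
import pandas as pd

from .exceptions import FormatError, ValidationError

__all__ = ["PSMRecord", "PSMTable", "PEPResult",
           "read_psm_table", "write_psm_table",
           "read_pep_table", "write_pep_table"]

REQUIRED_COLUMNS = ("psm_id", "score", "label", "in_group")

_LABEL_MAP = {"target": "target", "decoy": "decoy", "1": "target",
              "0": "decoy"}
_BOOL_MAP = {"0": False, "1": True, "true": True, "false": False}


@dataclass(frozen=True)
class PSMRecord:
    """A single scored peptide-spectrum match."""
    psm_id: str
    score: float
    label: str          # "target" or "decoy"
    in_group: bool


@dataclass
class PSMTable:
    """An ordered collection of PSM records.

    Backed by a DataFrame with columns ``psm_id`` (str), ``score`` (float),
    ``label`` ("target"/"decoy"), ``in_group`` (bool).  Ties in score are
    always broken by input order (stable sorts throughout the package).
    """

    df: pd.DataFrame
    provenance: str = ""

    def __post_init__(self):
        self.df = self.df.reset_index(drop=True)
        self.validate()

    # -- construction helpers -------------------------------------------------
    @classmethod
    def from_records(cls, records, provenance: str = "") -> "PSMTable":
        df = pd.DataFrame(
            {"psm_id": [r.psm_id for r in records],
             "score": [float(r.score) for r in records],
             "label": [r.label for r in records],
             "in_group": [bool(r.in_group) for r in records]})
        return cls(df, provenance)

    @classmethod
    def from_arrays(cls, psm_id, score, label, in_group,
                    provenance: str = "") -> "PSMTable":
        df = pd.DataFrame({"psm_id": np.asarray(psm_id, dtype=str),
                           "score": np.asarray(score, dtype=float),
                           "label": np.asarray(label, dtype=str),
                           "in_group": np.asarray(in_group, dtype=bool)})
        return cls(df, provenance)

    @property
    def records(self) -> list[PSMRecord]:
        return [PSMRecord(r.psm_id, float(r.score), r.label, bool(r.in_group))
                for r in self.df.itertuples(index=False)]

    def validate(self) -> None:
        df = self.df
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"PSM table missing column(s): {missing}")
        scores = df["score"].to_numpy(dtype=float)
        if not np.all(np.isfinite(scores)):
            bad = np.flatnonzero(~np.isfinite(scores))
            raise ValidationError(
                f"non-finite score at row(s) {bad[:5].tolist()}")
        if not df["label"].isin(["target", "decoy"]).all():
            bad = df.loc[~df["label"].isin(["target", "decoy"]), "label"]
            raise ValidationError(f"invalid label value(s): "
                                  f"{bad.unique()[:5].tolist()}")
        if df["psm_id"].duplicated().any():
            dup = df.loc[df["psm_id"].duplicated(), "psm_id"]
            raise ValidationError(
                f"duplicate psm_id value(s): {dup.unique()[:5].tolist()}")
        if len(df) > 0:
            n_t = int((df["label"] == "target").sum())
            n_d = len(df) - n_t
            if n_t < 1 or n_d < 1:
                raise ValidationError(
                    f"table needs >=1 target and >=1 decoy record "
                    f"(got {n_t} targets, {n_d} decoys)")

    # -- views ----------------------------------------------------------------
    @property
    def is_target(self) -> np.ndarray:
        return (self.df["label"] == "target").to_numpy()

    @property
    def in_group(self) -> np.ndarray:
        return self.df["in_group"].to_numpy(dtype=bool)

    @property
    def scores(self) -> np.ndarray:
        return self.df["score"].to_numpy(dtype=float)

    @property
    def target_scores(self) -> np.ndarray:
        return self.scores[self.is_target]

    @property
    def decoy_scores(self) -> np.ndarray:
        return self.scores[~self.is_target]

    @property
    def group_target_scores(self) -> np.ndarray:
        return self.scores[self.is_target & self.in_group]

    @property
    def group_target_ids(self) -> np.ndarray:
        m = self.is_target & self.in_group
        return self.df.loc[m, "psm_id"].to_numpy()

    @property
    def group_decoy_scores(self) -> np.ndarray:
        return self.scores[~self.is_target & self.in_group]

    @property
    def decoy_in_group(self) -> np.ndarray:
        return self.in_group[~self.is_target]

    def subset_group(self) -> "PSMTable":
        """Restrict to in-group records (used by the separate estimator)."""
        return PSMTable(self.df.loc[self.in_group].copy(),
                        provenance=self.provenance + " [group subset]")

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class PEPResult:
    """Per-target-PSM posterior error probabilities for one method.

    Rows are sorted by score descending (stable); ``ifdr`` at each row is
    the running mean of ``pep`` over rows at or above that score.
    """

    df: pd.DataFrame   # columns: psm_id, score, pep, ifdr
    method: str        # "combined" | "separate" | "transfer"
    model_diagnostics: Any = field(default=None, repr=False)

    def __post_init__(self):
        self.df = self.df.reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        df = self.df
        for c in ("psm_id", "score", "pep", "ifdr"):
            if c not in df.columns:
                raise FormatError(f"PEP result missing column: {c}")
        if self.method not in ("combined", "separate", "transfer"):
            raise ValidationError(f"unknown method: {self.method!r}")
        if len(df) == 0:
            return
        pep = df["pep"].to_numpy(float)
        ifdr = df["ifdr"].to_numpy(float)
        if np.any(pep < 0) or np.any(pep > 1) or not np.all(np.isfinite(pep)):
            raise ValidationError("pep values must lie in [0,1]")
        if np.any(ifdr < 0) or np.any(ifdr > 1):
            raise ValidationError("ifdr values must lie in [0,1]")
        score = df["score"].to_numpy(float)
        if np.any(np.diff(score) > 0):
            raise ValidationError("rows must be sorted by score descending")
        running = np.cumsum(pep) / np.arange(1, len(pep) + 1)
        if not np.allclose(ifdr, running, atol=1e-9, rtol=1e-9):
            raise ValidationError(
                "ifdr must equal the running mean of pep down the ranking")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_psm_table(path, column_map: Mapping[str, str] | None = None
                   ) -> PSMTable:
    """Read the generic TSV exchange format.

    ``column_map`` maps required names to the file's actual header names,
    e.g. ``{"score": "mascot_ion_score"}``.  ``label`` accepts
    target/decoy (case-insensitive) or 1/0; ``in_group`` accepts
    0/1/true/false.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    column_map = dict(column_map or {})
    rename = {column_map.get(c, c): c for c in REQUIRED_COLUMNS}
    present = {src: dst for src, dst in rename.items() if src in raw.columns}
    missing = [dst for src, dst in rename.items() if src not in raw.columns]
    if missing:
        raise FormatError(
            f"{path}: missing required column(s) {missing} "
            f"(header: {list(raw.columns)})")
    df = raw.rename(columns=present)[list(REQUIRED_COLUMNS)].copy()

    scores = pd.to_numeric(df["score"], errors="coerce")
    bad = ~np.isfinite(scores.to_numpy(dtype=float))
    if bad.any():
        lines = (np.flatnonzero(bad) + 2).tolist()  # +2: header + 1-based
        raise FormatError(
            f"{path}: unparseable or non-finite score at line(s) "
            f"{lines[:10]}")
    df["score"] = scores.astype(float)

    label = df["label"].str.strip().str.lower().map(_LABEL_MAP)
    if label.isna().any():
        lines = (np.flatnonzero(label.isna().to_numpy()) + 2).tolist()
        raise FormatError(
            f"{path}: label must be target/decoy/1/0; bad line(s) "
            f"{lines[:10]}")
    df["label"] = label

    flag = df["in_group"].str.strip().str.lower().map(_BOOL_MAP)
    if flag.isna().any():
        lines = (np.flatnonzero(flag.isna().to_numpy()) + 2).tolist()
        raise FormatError(
            f"{path}: in_group must be 0/1/true/false; bad line(s) "
            f"{lines[:10]}")
    df["in_group"] = flag.astype(bool)

    return PSMTable(df, provenance=str(path))


def write_psm_table(table: PSMTable, path) -> None:
    table.validate()
    out = table.df.copy()
    out["in_group"] = out["in_group"].astype(int)
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")


def write_pep_table(result: PEPResult, path) -> None:
    """Write a PEP result as TSV (psm_id, score, pep, ifdr, method).

    Floats are written with 17 significant digits, so reading the file back
    reproduces every value bit-for-bit.
    """
    result.validate()
    out = result.df[["psm_id", "score", "pep", "ifdr"]].copy()
    out["method"] = result.method
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_pep_table(path) -> PEPResult:
    df = pd.read_csv(path, sep="\t", dtype={"psm_id": str},
                     float_precision="round_trip")
    if len(df) == 0:
        return PEPResult(df=pd.DataFrame(
            columns=["psm_id", "score", "pep", "ifdr"]), method="combined")
    methods = df["method"].unique()
    if len(methods) != 1:
        raise FormatError(f"{path}: expected a single method, got {methods}")
    return PEPResult(df=df[["psm_id", "score", "pep", "ifdr"]],
                     method=str(methods[0]))
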