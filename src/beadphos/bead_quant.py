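"""Spectral-code assignment, per-code aggregation, and the synthesis QC gate.

Beads carry an embedded ratiometric lanthanide code; decoding assigns each
bead's measured ratio vector to the nearest reference vector (Euclidean),
subject to a maximum distance and a uniqueness requirement.  Downstream
statistics summarize assay-channel fluorescence per (code, condition,
replicate).  The QC gate removes codes whose starting signal is
indistinguishable from a phosphate-free negative-control peptide — the
signature of failed on-bead synthesis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .errors import ConfigurationError, InputError

logger = logging.getLogger(__name__)

UNASSIGNED = "unassigned"
REASON_TOO_FAR = "too-far"
REASON_TIE = "ambiguous-tie"

#: Relative tolerance within which two nearest-code distances count as a tie.
TIE_RTOL = 1e-9


@dataclass
class CodeTable:
    """Reference lanthanide-ratio vectors, one per spectral code."""

    codes: dict  # code_id -> np.ndarray of length L
    negative_control_code: str | None = None
    _matrix: np.ndarray = field(init=False, repr=False)
    _ids: list = field(init=False, repr=False)

    def __post_init__(self):
        if not self.codes:
            raise ConfigurationError("empty code table")
        self._ids = list(self.codes)
        self._matrix = np.asarray([np.asarray(self.codes[c], dtype=float) for c in self._ids])
        if self._matrix.ndim != 2:
            raise ConfigurationError("reference vectors must share one length")
        if (self._matrix < 0).any():
            raise ConfigurationError("reference vector components must be >= 0")
        d = cdist(self._matrix, self._matrix)
        np.fill_diagonal(d, np.inf)
        if len(self._ids) > 1 and d.min() == 0:
            raise ConfigurationError("reference vectors must be pairwise distinct")

    @property
    def n_channels(self) -> int:
        return self._matrix.shape[1]

    def min_spacing(self) -> float:
        if len(self._ids) < 2:
            return np.inf
        d = cdist(self._matrix, self._matrix)
        np.fill_diagonal(d, np.inf)
        return float(d.min())

    def default_max_distance(self) -> float:
        # half the minimum inter-reference spacing: conservative, parameter-light
        return self.min_spacing() / 2.0

    def to_frame(self) -> pd.DataFrame:
        cols = [f"l{i + 1}" for i in range(self.n_channels)]
        df = pd.DataFrame(self._matrix, columns=cols)
        df.insert(0, "code_id", self._ids)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, negative_control_code=None) -> "CodeTable":
        lcols = [c for c in df.columns if c.startswith("l") and c[1:].isdigit()]
        lcols = sorted(lcols, key=lambda c: int(c[1:]))
        if not lcols:
            raise ConfigurationError("code table has no lanthanide ratio columns l1..lL")
        codes = {row["code_id"]: row[lcols].to_numpy(dtype=float) for _, row in df.iterrows()}
        return cls(codes=codes, negative_control_code=negative_control_code)


def assign_code(bead_vector, codes: CodeTable, max_distance: float | None = None):
    """Assign one bead vector to its nearest reference code.

    Returns ``(code_id, None)`` on success, or ``(UNASSIGNED, reason)`` where
    reason is "too-far" or "ambiguous-tie".
    """
    vec = np.asarray(bead_vector, dtype=float)
    if vec.shape != (codes.n_channels,):
        raise InputError(f"bead vector length {vec.shape} != code table L={codes.n_channels}")
    if max_distance is None:
        max_distance = codes.default_max_distance()
    d = np.linalg.norm(codes._matrix - vec, axis=1)
    order = np.argsort(d)
    best = d[order[0]]
    if best > max_distance:
        return UNASSIGNED, REASON_TOO_FAR
    if len(d) > 1 and np.isclose(d[order[1]], best, rtol=TIE_RTOL, atol=0.0):
        return UNASSIGNED, REASON_TIE
    return codes._ids[order[0]], None


def assign_codes(beads: pd.DataFrame, codes: CodeTable, max_distance: float | None = None) -> pd.DataFrame:
    """Vectorized decoding of a bead table; adds ``code_id`` and ``assign_reason``.

    The bead table must carry lanthanide columns ``l1..lL``.
    """
    if max_distance is None:
        max_distance = codes.default_max_distance()
    lcols = [f"l{i + 1}" for i in range(codes.n_channels)]
    missing = [c for c in lcols if c not in beads.columns]
    if missing:
        raise InputError(f"bead table missing lanthanide columns: {missing}")
    vecs = beads[lcols].to_numpy(dtype=float)
    d = cdist(vecs, codes._matrix)
    nearest = np.argmin(d, axis=1)
    best = d[np.arange(len(d)), nearest]
    d_masked = d.copy()
    d_masked[np.arange(len(d)), nearest] = np.inf
    second = d_masked.min(axis=1) if d.shape[1] > 1 else np.full(len(d), np.inf)

    ids = np.asarray(codes._ids, dtype=object)
    out = beads.copy()
    code_col = ids[nearest].copy()
    reason = np.full(len(d), None, dtype=object)
    too_far = best > max_distance
    tie = ~too_far & np.isclose(second, best, rtol=TIE_RTOL, atol=0.0)
    code_col[too_far | tie] = UNASSIGNED
    reason[too_far] = REASON_TOO_FAR
    reason[tie] = REASON_TIE
    out["code_id"] = code_col
    out["assign_reason"] = reason
    n_un = int((too_far | tie).sum())
    if n_un:
        logger.info("assign_codes: %d/%d beads unassigned", n_un, len(out))
    return out


def clip_negative_intensities(beads: pd.DataFrame) -> pd.DataFrame:
    """Clip negative assay intensities to 0 (background subtraction artifacts)."""
    out = beads.copy()
    neg = out["intensity"] < 0
    if neg.any():
        logger.info("clipping %d negative intensities to 0", int(neg.sum()))
        out.loc[neg, "intensity"] = 0.0
    return out


def summarize_codes(
    beads: pd.DataFrame,
    statistic: str = "mean",
    group_cols: tuple = ("code_id", "condition", "replicate_id"),
) -> pd.DataFrame:
    """Aggregate per-bead intensities to one summary per (code, condition, replicate).

    ``statistic="mean"`` reports mean ± SD; ``"median"`` reports median ±
    median absolute deviation.  Beads flagged unassigned are dropped (logged).
    """
    if statistic not in ("mean", "median"):
        raise ConfigurationError(f"statistic must be 'mean' or 'median', got {statistic!r}")
    if "code_id" not in beads.columns:
        raise InputError("beads must carry code_id; run assign_codes first")
    data = beads[beads["code_id"] != UNASSIGNED]
    dropped = len(beads) - len(data)
    if dropped:
        logger.info("summarize_codes: dropping %d unassigned beads", dropped)
    if data.empty:
        raise InputError("no assigned beads to summarize")

    def _agg(x: pd.Series) -> pd.Series:
        v = x.to_numpy(dtype=float)
        if statistic == "mean":
            central = float(np.mean(v))
            disp = float(np.std(v, ddof=1)) if len(v) > 1 else 0.0
        else:
            central = float(np.median(v))
            disp = float(np.median(np.abs(v - np.median(v))))
        return pd.Series(
            {"n_beads": len(v), "central_intensity": central, "dispersion": disp}
        )

    cols = [c for c in group_cols if c in data.columns]
    out = data.groupby(cols, sort=True)["intensity"].apply(_agg).unstack().reset_index()
    out["n_beads"] = out["n_beads"].astype(int)
    return out


@dataclass(frozen=True)
class QCReport:
    code_id: str
    start_intensity: float
    threshold: float
    passed: bool


def qc_gate(
    beads_at_start: pd.DataFrame,
    negative_control_code: str,
    multiplier: float = 1.5,
    code_statistic: str = "median",
) -> pd.DataFrame:
    """Flag codes whose starting signal matches the negative control.

    The threshold is computed from the *per-bead* negative-control intensity
    distribution at the initial condition: ``median + multiplier * SD``.
    Each code's starting intensity (median per bead by default, mean
    selectable) is compared against it; codes below the threshold fail and
    are excluded downstream.

    Returns a DataFrame with columns code_id, start_intensity, threshold,
    passed.  The negative-control code itself is included (it normally fails).
    """
    if "code_id" not in beads_at_start.columns:
        raise InputError("beads must carry code_id")
    neg = beads_at_start.loc[
        beads_at_start["code_id"] == negative_control_code, "intensity"
    ].to_numpy(dtype=float)
    if len(neg) < 2:
        raise InputError(
            f"negative-control code {negative_control_code!r} has {len(neg)} beads at the "
            "initial condition; need >= 2 to compute the gate"
        )
    threshold = float(np.median(neg) + multiplier * np.std(neg, ddof=1))

    agg = np.median if code_statistic == "median" else np.mean
    rows = []
    for code, grp in beads_at_start.groupby("code_id", sort=True):
        if code == UNASSIGNED:
            continue
        start = float(agg(grp["intensity"].to_numpy(dtype=float)))
        rows.append(
            {
                "code_id": code,
                "start_intensity": start,
                "threshold": threshold,
                "passed": bool(start >= threshold),
            }
        )
    report = pd.DataFrame(rows, columns=["code_id", "start_intensity", "threshold", "passed"])
    n_fail = int((~report["passed"]).sum())
    logger.info("qc_gate: %d/%d codes fail (threshold %.3f)", n_fail, len(report), threshold)
    return report
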