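"""Phosphosite sequence-context analytics and RVxF short-linear-motif scanning.

Windows are odd-length strings centered on the phospho residue, padded with
``_`` beyond the protein termini; pads are excluded from all counts.
Frequency logos give per-position residue frequencies; enrichment logos
contrast a foreground set against a background (typically non-regulated
sites) with a per-cell two-proportion z-test, reporting both enrichment and
deselection.

The PP1-docking motif is scanned with the generalized pattern

    [RK] x{0,1} [VI] x [FW]        (x != P in core positions by default)

covering both the 4-residue (RVxF) and 5-residue (RxVxF) registers; a strict
mode restricts to the literal R/V/F letters.  Lowercase s/t/y in a sequence
mark phospho-residues and are annotated on matches.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError

logger = logging.getLogger(__name__)

PAD = "_"
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
CENTER_ACCEPTORS = set("STY")


def extract_window(sequence: str, position: int, flank: int = 7, pad_char: str = PAD) -> str:
    """Centered window of width 2*flank+1 around a phosphosite (1-based)."""
    if not 1 <= position <= len(sequence):
        raise InputError(f"position {position} outside sequence of length {len(sequence)}")
    center = sequence[position - 1]
    if center.upper() not in CENTER_ACCEPTORS:
        raise InputError(f"residue at position {position} is {center!r}, not S/T/Y")
    left = max(0, position - 1 - flank)
    right = min(len(sequence), position + flank)
    window = sequence[left:right]
    window = pad_char * (flank - (position - 1 - left)) + window
    window = window + pad_char * (2 * flank + 1 - len(window))
    return window


@dataclass
class LogoMatrix:
    """Position x residue matrices for a logo.

    ``frequency`` rows are per-position residue frequencies over non-pad
    symbols; ``enrichment`` (foreground minus background frequency) and
    ``p_value`` are present for enrichment logos.  Positions are labeled
    -k..+k around the center.
    """

    frequency: pd.DataFrame
    foreground_n: int
    background_n: int = 0
    enrichment: pd.DataFrame | None = None
    fold: pd.DataFrame | None = None
    p_value: pd.DataFrame | None = None
    counts: pd.DataFrame = field(default_factory=pd.DataFrame)

    def information_content(self) -> pd.Series:
        """Per-position information content, log2(20) minus entropy (bits)."""
        f = self.frequency.to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            ent = -np.nansum(np.where(f > 0, f * np.log2(f), 0.0), axis=1)
        return pd.Series(np.log2(20) - ent, index=self.frequency.index)

    def significant_cells(self, alpha: float = 0.05) -> pd.DataFrame:
        if self.p_value is None:
            raise InputError("not an enrichment logo")
        return self.p_value < alpha


def _position_labels(width: int) -> list:
    k = width // 2
    return list(range(-k, k + 1))


def _count_matrix(windows) -> pd.DataFrame:
    widths = {len(w) for w in windows}
    if len(widths) != 1:
        raise InputError(f"mixed window lengths: {sorted(widths)}")
    (width,) = widths
    if width % 2 == 0:
        raise InputError("windows must have odd length")
    labels = _position_labels(width)
    counts = pd.DataFrame(0, index=labels, columns=list(AMINO_ACIDS), dtype=float)
    for w in windows:
        for pos, ch in zip(labels, w):
            ch = ch.upper()
            if ch == PAD:
                continue
            if ch in counts.columns:
                counts.loc[pos, ch] += 1
    return counts


def frequency_logo(windows) -> LogoMatrix:
    """Per-position residue frequencies over non-pad symbols."""
    windows = list(windows)
    if not windows:
        raise InputError("frequency_logo requires >= 1 window")
    counts = _count_matrix(windows)
    totals = counts.sum(axis=1)
    freq = counts.div(totals.replace(0, np.nan), axis=0).fillna(0.0)
    return LogoMatrix(frequency=freq, foreground_n=len(windows), counts=counts)


def two_proportion_ztest(x1: float, n1: float, x2: float, n2: float) -> float:
    """Two-sided pooled two-proportion z-test p-value.

    Identical proportions (including the all-zero case) give p = 1.
    """
    if n1 <= 0 or n2 <= 0:
        return 1.0
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    if se == 0:
        return 1.0
    z = (p1 - p2) / se
    return float(2 * stats.norm.sf(abs(z)))


def fisher_cell_test(x1: float, n1: float, x2: float, n2: float) -> float:
    """Fisher exact p-value for one logo cell (optional alternative)."""
    table = [[int(x1), int(n1 - x1)], [int(x2), int(n2 - x2)]]
    return float(stats.fisher_exact(table)[1])


def enrichment_logo(
    foreground,
    background,
    alpha: float = 0.05,
    pseudocount: float | None = None,
    test: str = "ztest",
) -> LogoMatrix:
    """Foreground-vs-background enrichment logo.

    Per (position, residue) cell: enrichment = f_fg - f_bg (signed, so
    deselection appears as negative values), fold = (f_fg + eps)/(f_bg + eps)
    with Laplace-style eps = 1/(n+20) unless overridden, and a two-sided
    two-proportion z-test p-value ("fisher" selects the exact test).
    """
    fg = list(foreground)
    bg = list(background)
    if not fg or not bg:
        raise InputError("both foreground and background must be nonempty")
    if len(bg) < 20:
        logger.warning("background has only %d windows; enrichment unstable", len(bg))
    cf = _count_matrix(fg)
    cb = _count_matrix(bg)
    if list(cf.index) != list(cb.index):
        raise InputError("foreground and background window lengths differ")
    nf = cf.sum(axis=1)
    nb = cb.sum(axis=1)
    ff = cf.div(nf.replace(0, np.nan), axis=0).fillna(0.0)
    fb = cb.div(nb.replace(0, np.nan), axis=0).fillna(0.0)

    eps_f = pseudocount if pseudocount is not None else 1.0 / (len(fg) + 20)
    eps_b = pseudocount if pseudocount is not None else 1.0 / (len(bg) + 20)
    fold = (ff + eps_f) / (fb + eps_b)

    testfun = two_proportion_ztest if test == "ztest" else fisher_cell_test
    pvals = pd.DataFrame(1.0, index=cf.index, columns=cf.columns)
    for pos in cf.index:
        for res in cf.columns:
            pvals.loc[pos, res] = testfun(
                cf.loc[pos, res], nf.loc[pos], cb.loc[pos, res], nb.loc[pos]
            )
    return LogoMatrix(
        frequency=ff,
        foreground_n=len(fg),
        background_n=len(bg),
        enrichment=ff - fb,
        fold=fold,
        p_value=pvals,
        counts=cf,
    )


def classify_proline_directed(window: str) -> bool:
    """True iff the residue immediately C-terminal of the center is proline."""
    if len(window) % 2 == 0:
        raise InputError("window must have odd length")
    center = len(window) // 2
    if center + 1 >= len(window):
        return False
    return window[center + 1].upper() == "P"


@dataclass(frozen=True)
class MotifMatch:
    protein_id: str
    start: int  # 1-based inclusive
    end: int
    matched_text: str
    variant: str  # "RVxF" or "RxVxF"
    phospho_positions_inside: tuple = ()
    predicted_ddg: float | None = None


def _class_match(ch: str, allowed: str, strict_letter: str, strict: bool) -> bool:
    up = ch.upper()
    if up == "X":
        return False  # unknown residue never matches
    if strict:
        return up == strict_letter
    return up in allowed


def _x_ok(ch: str, exclude_proline: bool) -> bool:
    up = ch.upper()
    if up == "X":
        return False
    return not (exclude_proline and up == "P")


def scan_rvxf(
    sequence: str,
    protein_id: str = "",
    strict: bool = False,
    exclude_proline_core: bool = True,
) -> list:
    """All (possibly overlapping) matches of the Rx0-1VxF docking motif.

    Default residue classes: [RK] at the anchor, [VI] at the valine slot,
    [FW] at the aromatic slot; ``strict=True`` restricts to the literal R/V/F.
    ``exclude_proline_core`` disallows proline at the x positions.  Lowercase
    s/t/y denote phospho-residues; their absolute positions within offsets
    -1..+4 of each core are recorded.
    """
    matches = []
    n = len(sequence)
    for i in range(n):
        # 4-residue register: [RK] [VI] x [FW]
        if i + 3 < n:
            if (
                _class_match(sequence[i], "RK", "R", strict)
                and _class_match(sequence[i + 1], "VI", "V", strict)
                and _x_ok(sequence[i + 2], exclude_proline_core)
                and _class_match(sequence[i + 3], "FW", "F", strict)
            ):
                matches.append(_make_match(sequence, protein_id, i, 4, "RVxF"))
        # 5-residue register: [RK] x [VI] x [FW]
        if i + 4 < n:
            if (
                _class_match(sequence[i], "RK", "R", strict)
                and _x_ok(sequence[i + 1], exclude_proline_core)
                and _class_match(sequence[i + 2], "VI", "V", strict)
                and _x_ok(sequence[i + 3], exclude_proline_core)
                and _class_match(sequence[i + 4], "FW", "F", strict)
            ):
                matches.append(_make_match(sequence, protein_id, i, 5, "RxVxF"))
    return matches


def _make_match(sequence: str, protein_id: str, i: int, length: int, variant: str) -> MotifMatch:
    start, end = i + 1, i + length
    lo = max(1, start - 1)
    hi = min(len(sequence), start + 4)
    phospho = tuple(pos for pos in range(lo, hi + 1) if sequence[pos - 1] in "sty")
    return MotifMatch(
        protein_id=protein_id,
        start=start,
        end=end,
        matched_text=sequence[i : i + length],
        variant=variant,
        phospho_positions_inside=phospho,
    )


def matches_to_frame(matches) -> pd.DataFrame:
    """BED-like table of motif matches."""
    return pd.DataFrame(
        [
            {
                "protein_id": m.protein_id,
                "start": m.start,
                "end": m.end,
                "strand": ".",
                "variant": m.variant,
                "matched_text": m.matched_text,
                "phospho_positions": ";".join(map(str, m.phospho_positions_inside)),
                "predicted_ddg": m.predicted_ddg if m.predicted_ddg is not None else np.nan,
            }
            for m in matches
        ]
    )


def predict_motif_ddg(match: MotifMatch, table, window_sequence: str, window_start: int):
    """Additive ΔΔG prediction for a motif instance against a substitution table.

    ``table`` is a :class:`~beadphos.binding_affinity.SubstitutionTable`;
    ``window_sequence`` is the protein region containing the match (canonical
    phospho notation) and ``window_start`` its 1-based start in the protein.
    The match is registered to the table's reference frame by aligning motif
    starts; per-position ΔΔG cells for deviating residues are summed
    (additivity assumed).  Returns ``(ddg, partial)`` where ``partial`` is
    True when any deviating cell is unmeasured.
    """
    offset = match.start - window_start + 1 - table.motif_start
    total = 0.0
    partial = False
    for ref_pos in range(1, len(table.reference) + 1):
        wpos = ref_pos + offset
        if not 1 <= wpos <= len(window_sequence):
            raise InputError("match window does not cover the table's reference frame")
        res = window_sequence[wpos - 1]
        ref = table.reference[ref_pos - 1]
        if res == ref:
            continue
        val = table.cell(ref_pos, res)
        if np.isnan(val):
            partial = True
        else:
            total += val
    return total, partial


def stratify_by_motif_distance(
    sites: pd.DataFrame,
    matches,
    boundary: int = 1000,
    mode: str = "fixed",
    flank: int = 7,
    sequence: str | None = None,
) -> dict:
    """Split one protein's sites into near/far groups relative to its motif.

    ``mode="fixed"`` splits at an absolute coordinate (sites with position
    <= boundary are near, inclusive); ``mode="radial"`` uses distance from
    the nearest motif core (<= boundary near).  Sites must carry ``position``
    (and ``window`` unless ``sequence`` is given).  Returns group site tables
    and, when windows are available, per-group frequency logos.
    """
    if not matches:
        logger.warning("no motif match: all sites grouped 'far'")
    positions = sites["position"].to_numpy(dtype=float)
    if mode == "fixed":
        near_mask = positions <= boundary
    elif mode == "radial":
        if matches:
            centers = np.asarray([(m.start + m.end) / 2.0 for m in matches])
            dist = np.min(np.abs(positions[:, None] - centers[None, :]), axis=1)
            near_mask = dist <= boundary
        else:
            near_mask = np.zeros(len(positions), dtype=bool)
    else:
        raise InputError(f"unknown mode {mode!r}")

    near = sites[near_mask]
    far = sites[~near_mask]
    out = {"near": near, "far": far}
    for name, grp in (("near", near), ("far", far)):
        windows = None
        if "window" in grp.columns:
            windows = grp["window"].tolist()
        elif sequence is not None:
            windows = [extract_window(sequence, int(p), flank) for p in grp["position"]]
        if windows:
            out[f"{name}_logo"] = frequency_logo(windows)
    return out
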