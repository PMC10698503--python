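"""Langmuir isotherm fitting and ΔΔG ledgers for bead-based binding assays.

Concentration-dependent binding of a protein to bead-displayed peptides is
modeled by the single-site Langmuir isotherm

    y(c) = y_max * c / (c + K_d)

Weak binders never saturate within the assay's concentration range, so both
parameters are not jointly identifiable for them.  The global scheme assumes
equal binding stoichiometry across peptides: peptides that do saturate are
fit locally (both parameters), their mean y_max becomes a shared saturation
value, and every curve is then refit with only K_d free.

ΔΔG versus a reference sequence is R*T*ln(K_d,variant / K_d,reference) in
kcal/mol at T = 298.15 K by default; positive values mean weaker binding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit, minimize_scalar

from .errors import ConflictError, InputError

logger = logging.getLogger(__name__)

#: Gas constant in kcal / (mol * K).
R_KCAL = 1.9872e-3
#: Default absolute temperature (K).
T_DEFAULT = 298.15

#: Default titration grid in nM.
DEFAULT_CONC_GRID = (0.0, 15.0, 31.0, 62.0, 125.0, 250.0, 500.0, 1000.0, 2000.0)

KD_LOWER = 1e-2
KD_UPPER = 1e6
#: K_d estimates above this multiple of the top assay concentration are
#: reported as lower bounds only (censored).
CENSOR_FACTOR = 5.0


def langmuir(c, y_max, kd):
    c = np.asarray(c, dtype=float)
    return y_max * c / (c + kd)


@dataclass
class IsothermFit:
    peptide_id: str = ""
    replicate_id: str = ""
    y_max: float = np.nan
    kd: float = np.nan
    y_max_fixed: bool = False
    residual_norm: float = np.nan
    fit_ok: bool = False
    censored: bool = False
    message: str = ""


def _check_curve(conc, intensity):
    c = np.asarray(conc, dtype=float)
    y = np.asarray(intensity, dtype=float)
    if c.shape != y.shape or c.ndim != 1:
        raise InputError("concentrations and intensities must be 1-D and equal length")
    if not np.all(np.isfinite(y)):
        raise InputError("non-finite intensities in binding curve")
    if not np.all(np.diff(c) > 0) or (c < 0).any():
        raise InputError("concentrations must be nonnegative and strictly increasing")
    return c, y


def fit_langmuir_local(conc, intensity, peptide_id="", replicate_id="") -> IsothermFit:
    """Two-parameter (y_max, K_d) bounded least-squares Langmuir fit."""
    c, y = _check_curve(conc, intensity)
    if len(c) < 4:
        raise InputError("local fit requires >= 4 concentration points")
    ymax0 = float(np.max(y))
    fit = IsothermFit(peptide_id=peptide_id, replicate_id=replicate_id)
    if ymax0 <= 0:
        fit.message = "non-positive signal"
        return fit
    # a monotonically decreasing curve cannot be Langmuir binding
    nz = c > 0
    if nz.sum() >= 2 and np.all(np.diff(y[nz]) < 0):
        logger.warning("%s/%s: monotonically decreasing curve", peptide_id, replicate_id)
        fit.message = "monotonically decreasing"
        return fit
    half = np.abs(y - ymax0 / 2.0)
    kd0 = float(c[np.argmin(half)])
    kd0 = min(max(kd0, KD_LOWER * 10), KD_UPPER / 10)
    try:
        popt, _ = curve_fit(
            langmuir,
            c,
            y,
            p0=(ymax0, kd0),
            bounds=((1e-12, KD_LOWER), (10.0 * ymax0, KD_UPPER)),
            maxfev=10000,
        )
    except (RuntimeError, ValueError) as exc:
        fit.message = f"solver failure: {exc}"
        return fit
    fit.y_max, fit.kd = (float(v) for v in popt)
    fit.residual_norm = float(np.linalg.norm(langmuir(c, *popt) - y))
    fit.fit_ok = True
    fit.censored = fit.kd > CENSOR_FACTOR * c[-1]
    return fit


def select_saturating(
    curves: dict,
    intensity_threshold: float | None = 12000.0,
    relative_quantile: float | None = None,
) -> list:
    """Peptides whose top-concentration intensity marks saturation.

    ``curves`` maps peptide_id -> (conc, intensity) arrays.  By default an
    absolute threshold on the final intensity is applied (instrument-scale
    specific); ``relative_quantile`` switches to a percentile of the
    top-concentration intensities across peptides (portable across scales).
    """
    if not curves:
        raise InputError("no curves supplied")
    finals = {pid: float(np.asarray(y)[-1]) for pid, (c, y) in curves.items()}
    if relative_quantile is not None:
        thr = float(np.percentile(list(finals.values()), relative_quantile))
        selected = [pid for pid, v in finals.items() if v >= thr]
    else:
        if intensity_threshold is None:
            raise InputError("either intensity_threshold or relative_quantile is required")
        selected = [pid for pid, v in finals.items() if v > intensity_threshold]
    if not selected:
        raise InputError("no saturating peptides: shared y_max is undefined")
    return sorted(selected)


def global_ymax(fits) -> float:
    """Arithmetic mean of locally fitted y_max over the saturating subset."""
    vals = [f.y_max for f in fits if f.fit_ok]
    if not vals:
        raise InputError("global y_max requires >= 1 successful local fit")
    return float(np.mean(vals))


def fit_kd_global(conc, intensity, shared_ymax: float, peptide_id="", replicate_id="") -> IsothermFit:
    """One-parameter K_d fit with the saturation intensity frozen.

    Minimizes the sum of squared residuals over log10(K_d) with a bounded
    scalar solver; censoring flags estimates beyond the assay's dynamic range
    or sitting at the upper K_d bound.
    """
    if not shared_ymax > 0:
        raise InputError("shared_ymax must be positive")
    c, y = _check_curve(conc, intensity)

    def sse(log10_kd):
        return float(np.sum((langmuir(c, shared_ymax, 10.0 ** log10_kd) - y) ** 2))

    res = minimize_scalar(
        sse, bounds=(np.log10(KD_LOWER), np.log10(KD_UPPER)), method="bounded",
        options={"xatol": 1e-10},
    )
    kd = float(10.0 ** res.x)
    fit = IsothermFit(
        peptide_id=peptide_id,
        replicate_id=replicate_id,
        y_max=float(shared_ymax),
        kd=kd,
        y_max_fixed=True,
        residual_norm=float(np.sqrt(res.fun)),
        fit_ok=bool(res.success),
    )
    at_upper = kd >= KD_UPPER * 0.99
    fit.censored = at_upper or kd > CENSOR_FACTOR * c[-1]
    if at_upper:
        fit.message = "K_d at upper bound: lower-bound-only affinity"
    return fit


def aggregate_kd(kd_values, mode: str = "mean", log_space: bool = False):
    """Aggregate replicate K_d values; returns ``(kd_final, spread)``.

    ``mode`` is "mean" or "median"; ``log_space=True`` aggregates log10(K_d)
    and back-transforms (geometric statistics), reducing the upward bias of a
    linear mean under multiplicative error.
    """
    v = np.asarray(list(kd_values), dtype=float)
    if v.size == 0:
        raise InputError("aggregate_kd requires >= 1 replicate")
    if (v <= 0).any():
        raise InputError("K_d values must be positive")
    if log_space:
        lv = np.log10(v)
        central = np.mean(lv) if mode == "mean" else np.median(lv)
        spread = float(np.std(lv, ddof=1)) if v.size > 1 else 0.0
        return float(10.0 ** central), spread
    central = np.mean(v) if mode == "mean" else np.median(v)
    spread = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
    return float(central), spread


def delta_delta_g(kd_variant: float, kd_reference: float, temperature: float = T_DEFAULT) -> float:
    """ΔΔG = R*T*ln(K_d,variant / K_d,reference), kcal/mol; positive = weaker."""
    if kd_variant <= 0 or kd_reference <= 0:
        raise InputError("K_d values must be positive")
    return R_KCAL * temperature * float(np.log(kd_variant / kd_reference))


def kd_from_ddg(ddg: float, kd_reference: float, temperature: float = T_DEFAULT) -> float:
    """Inverse of :func:`delta_delta_g` (used to plant affinity truths)."""
    return kd_reference * float(np.exp(ddg / (R_KCAL * temperature)))


@dataclass
class SubstitutionTable:
    """ΔΔG per (reference position, substituted residue), relative to a reference.

    ``reference`` is the reference peptide in canonical notation (lowercase =
    phospho); ``motif_start`` anchors the motif's first core position within
    it (1-based).  ``ddg`` is a DataFrame indexed by reference position with
    residue columns (lowercase letters denote phospho-residues); NaN marks
    cells not measured.
    """

    reference: str
    motif_start: int
    ddg: pd.DataFrame = field(default_factory=pd.DataFrame)

    def cell(self, position: int, residue: str) -> float:
        try:
            return float(self.ddg.loc[position, residue])
        except KeyError:
            return np.nan


def substitution_table(
    affinities: pd.DataFrame,
    annotations: dict,
    reference_id: str,
    reference_sequence: str,
    motif_start: int = 1,
    temperature: float = T_DEFAULT,
) -> SubstitutionTable:
    """Assemble a position x residue ΔΔG matrix from per-peptide affinities.

    ``affinities`` needs columns peptide_id and kd_final.  ``annotations``
    maps each variant peptide_id to ``(position, residue)`` — its single
    deviation from the reference (lowercase residue = phospho).  Reference
    cells are set to 0; unmeasured cells stay NaN.  Two peptides claiming the
    same cell raise :class:`ConflictError`.
    """
    kd = affinities.set_index("peptide_id")["kd_final"]
    if reference_id not in kd.index:
        raise InputError(f"reference peptide {reference_id!r} absent from affinities")
    kd_ref = float(kd.loc[reference_id])

    positions = sorted(
        {pos for pos, _ in annotations.values()}
        | set(range(1, len(reference_sequence) + 1))
    )
    residues = sorted({res for _, res in annotations.values()})
    table = pd.DataFrame(np.nan, index=positions, columns=residues, dtype=float)

    claimed: dict = {}
    for pid, (pos, res) in annotations.items():
        if pid == reference_id:
            continue
        if pid not in kd.index:
            logger.warning("substitution_table: %s has no affinity; cell left absent", pid)
            continue
        key = (pos, res)
        if key in claimed:
            raise ConflictError(f"cell {key} claimed by both {claimed[key]!r} and {pid!r}")
        claimed[key] = pid
        if res not in table.columns:
            table[res] = np.nan
        table.loc[pos, res] = delta_delta_g(float(kd.loc[pid]), kd_ref, temperature)

    # reference residues define the zero diagonal
    for pos in range(1, len(reference_sequence) + 1):
        res = reference_sequence[pos - 1]
        if res not in table.columns:
            table[res] = np.nan
        table.loc[pos, res] = 0.0
    table = table[sorted(table.columns)]
    return SubstitutionTable(reference=reference_sequence, motif_start=motif_start, ddg=table)


def fit_experiment(
    summaries: pd.DataFrame,
    saturation_threshold: float | None = None,
    relative_quantile: float | None = 75.0,
    aggregate_mode: str = "mean",
    reference_peptide: str | None = None,
    code_to_peptide: dict | None = None,
    temperature: float = T_DEFAULT,
) -> pd.DataFrame:
    """Full global-fit pipeline over a summarized titration table.

    ``summaries`` carries code_id, condition (nM), replicate_id,
    central_intensity.  Per replicate: local fits -> saturating subset ->
    shared y_max -> one-parameter K_d refits.  K_d is then aggregated across
    replicates, and ΔΔG computed against ``reference_peptide`` when given.

    ``saturation_threshold`` selects the absolute intensity rule (e.g. the
    12,000-count instrument value); the default uses the ``relative_quantile``
    of top-concentration intensities instead.
    """
    req = {"code_id", "condition", "replicate_id", "central_intensity"}
    missing = req - set(summaries.columns)
    if missing:
        raise InputError(f"summary table missing columns: {sorted(missing)}")

    per_rep_kd: dict = {}
    censored: dict = {}
    shared_ymaxes = []
    for rep, grp in summaries.groupby("replicate_id", sort=True):
        curves = {}
        for code, sub in grp.groupby("code_id", sort=True):
            sub = sub.sort_values("condition")
            curves[code] = (
                sub["condition"].to_numpy(dtype=float),
                sub["central_intensity"].to_numpy(dtype=float),
            )
        local = {}
        for pid, (c, y) in curves.items():
            f = fit_langmuir_local(c, y, peptide_id=pid, replicate_id=str(rep))
            if f.fit_ok:
                local[pid] = f
        if saturation_threshold is not None:
            sat = select_saturating(curves, intensity_threshold=saturation_threshold)
        else:
            sat = select_saturating(
                curves, relative_quantile=relative_quantile, intensity_threshold=None
            )
        sat_fits = [local[pid] for pid in sat if pid in local]
        ymax = global_ymax(sat_fits)
        shared_ymaxes.append(ymax)
        for pid, (c, y) in curves.items():
            f = fit_kd_global(c, y, ymax, peptide_id=pid, replicate_id=str(rep))
            per_rep_kd.setdefault(pid, []).append(f.kd)
            censored.setdefault(pid, []).append(f.censored)

    rows = []
    for pid in sorted(per_rep_kd):
        kd_final, spread = aggregate_kd(per_rep_kd[pid], mode=aggregate_mode)
        rows.append(
            {
                "peptide_id": code_to_peptide.get(pid, pid) if code_to_peptide else pid,
                "kd_per_rep": ";".join(f"{v:.6g}" for v in per_rep_kd[pid]),
                "kd_final": kd_final,
                "kd_spread": spread,
                "censored": bool(any(censored[pid])),
                "shared_ymax": float(np.mean(shared_ymaxes)),
            }
        )
    out = pd.DataFrame(rows)
    if reference_peptide is not None:
        ref_rows = out[out["peptide_id"] == reference_peptide]
        if ref_rows.empty:
            raise InputError(f"reference peptide {reference_peptide!r} not in results")
        kd_ref = float(ref_rows["kd_final"].iloc[0])
        out["ddG"] = [delta_delta_g(v, kd_ref, temperature) for v in out["kd_final"]]
        out["reference_id"] = reference_peptide
    return out
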