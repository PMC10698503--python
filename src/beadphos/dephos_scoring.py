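"""Dephosphorylation scores, exponential kinetics, and comparative statistics.

The per-peptide dephosphorylation score for one experiment is

    score = 1 - mean(intensity over the last ``n_final`` time points) / intensity(t=0)

so 0 means no loss of phospho-signal and 1 means complete dephosphorylation.
Scores above 1 are impossible; scores below 0 (signal increase) are retained
and flagged because they diagnose staining artifacts.

Kinetics are summarized, where the decay is well described by a single
exponential, as I(t) = C + A*exp(-k*t) with all three parameters
nonnegative.  The score never depends on the fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import InputError, UndefinedScoreError

logger = logging.getLogger(__name__)

#: Default assay time grid in minutes.
DEFAULT_TIME_GRID = (0.0, 15.0, 30.0, 60.0, 120.0, 240.0)


@dataclass
class DephosResult:
    """Aggregated dephosphorylation outcome for one peptide x enzyme."""

    peptide_id: str
    enzyme: str
    score_per_replicate: list
    score_mean: float
    score_sd: float
    rate_k: float | None = None
    rate_k_sd: float | None = None
    amplitude: float | None = None
    baseline: float | None = None
    fit_rmse: float | None = None
    fit_ok: bool = False
    low_confidence: bool = False


def _check_timecourse(times, intensities):
    t = np.asarray(times, dtype=float)
    y = np.asarray(intensities, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise InputError("times and intensities must be 1-D and equal length")
    if not np.all(np.isfinite(y)):
        raise InputError("non-finite intensities in time course")
    if not np.all(np.diff(t) > 0):
        raise InputError("times must be strictly increasing")
    if t[0] != 0:
        raise InputError("time course must start at t = 0")
    return t, y


def dephos_score(times, intensities, n_final: int = 3) -> float:
    """1 minus the late-signal / initial-signal ratio for one time course."""
    t, y = _check_timecourse(times, intensities)
    if len(y) < n_final + 1:
        raise InputError(f"need at least {n_final + 1} points, got {len(y)}")
    if y[0] <= 0:
        raise UndefinedScoreError("intensity at t = 0 must be positive")
    final = float(np.mean(y[-n_final:]))
    return 1.0 - final / float(y[0])


def _exp_model(t, A, k, C):
    return C + A * np.exp(-k * t)


def fit_exponential(times, intensities):
    """Bounded least-squares fit of I(t) = C + A*exp(-k*t).

    Returns ``(A, k, C, rmse, fit_ok)``.  Initialization: A = I(0) - I(end),
    C = I(end), and k from a log-linear regression on baseline-subtracted
    values.  ``fit_ok`` is False when the solver fails or k sits at its lower
    bound (no resolvable decay); in that case k should be treated as absent.
    """
    t, y = _check_timecourse(times, intensities)
    if len(y) < 4:
        raise InputError("kinetic fit requires >= 4 points")
    if (y < 0).any():
        raise InputError("kinetic fit requires nonnegative intensities")

    A0 = max(y[0] - y[-1], 1e-12)
    C0 = max(y[-1], 0.0)
    # log-linear initial rate estimate on baseline-subtracted values
    resid = y - C0
    mask = (resid > 0) & (t >= 0)
    if mask.sum() >= 2:
        slope = np.polyfit(t[mask], np.log(resid[mask]), 1)[0]
        k0 = max(-slope, 1e-6)
    else:
        k0 = 1e-3
    try:
        popt, _ = curve_fit(
            _exp_model,
            t,
            y,
            p0=(A0, k0, C0),
            bounds=((0.0, 0.0, 0.0), (np.inf, np.inf, np.inf)),
            maxfev=10000,
        )
    except (RuntimeError, ValueError):
        return np.nan, np.nan, np.nan, np.nan, False
    A, k, C = (float(v) for v in popt)
    rmse = float(np.sqrt(np.mean((_exp_model(t, A, k, C) - y) ** 2)))
    # k or A at (numerically on) the lower bound means no decay was resolved:
    # with A ~ 0 the rate is unidentifiable even if the solver reports one
    fit_ok = k > 1e-9 and A > 1e-9 * max(float(np.max(y)), 1.0)
    return A, k, C, rmse, fit_ok


def aggregate_replicates(
    peptide_id: str,
    enzyme: str,
    scores,
    rates=None,
) -> DephosResult:
    """Mean/SD of scores (and, optionally, fitted rates) across replicates.

    A single replicate yields SD = 0 with ``low_confidence=True``.  Rates
    are averaged over replicates whose fit succeeded; if none did, the rate
    is absent.
    """
    scores = [float(s) for s in scores]
    if not scores:
        raise InputError("aggregate_replicates requires >= 1 replicate score")
    mean = float(np.mean(scores))
    sd = float(np.std(scores, ddof=1)) if len(scores) > 1 else 0.0
    rate_k = rate_sd = None
    if rates:
        ok = [r for r in rates if r is not None and np.isfinite(r)]
        if ok:
            rate_k = float(np.mean(ok))
            rate_sd = float(np.std(ok, ddof=1)) if len(ok) > 1 else 0.0
    return DephosResult(
        peptide_id=peptide_id,
        enzyme=enzyme,
        score_per_replicate=scores,
        score_mean=mean,
        score_sd=sd,
        rate_k=rate_k,
        rate_k_sd=rate_sd,
        fit_ok=rate_k is not None,
        low_confidence=len(scores) < 2,
    )


def score_experiment(
    summaries: pd.DataFrame,
    enzyme: str,
    qc_passed=None,
    n_final: int = 3,
    fit_kinetics: bool = True,
    code_to_peptide: dict | None = None,
) -> pd.DataFrame:
    """Score every code in a summarized time-course table and aggregate replicates.

    ``summaries`` must carry code_id, condition (minutes), replicate_id and
    central_intensity (from :func:`beadphos.bead_quant.summarize_codes`).
    ``qc_passed``, if given, restricts scoring to that set of code ids.

    Returns one row per code with score_mean, score_sd, per-replicate scores,
    and averaged kinetic parameters.
    """
    req = {"code_id", "condition", "replicate_id", "central_intensity"}
    missing = req - set(summaries.columns)
    if missing:
        raise InputError(f"summary table missing columns: {sorted(missing)}")
    data = summaries
    if qc_passed is not None:
        qc_passed = set(qc_passed)
        data = data[data["code_id"].isin(qc_passed)]

    rows = []
    for code, grp in data.groupby("code_id", sort=True):
        scores, rates = [], []
        fit_pars = []
        for _, rep in grp.groupby("replicate_id", sort=True):
            rep = rep.sort_values("condition")
            t = rep["condition"].to_numpy(dtype=float)
            y = rep["central_intensity"].to_numpy(dtype=float)
            try:
                scores.append(dephos_score(t, y, n_final=n_final))
            except (InputError, UndefinedScoreError) as exc:
                logger.warning("code %s replicate skipped: %s", code, exc)
                continue
            if fit_kinetics and len(y) >= 4:
                A, k, C, rmse, ok = fit_exponential(t, y)
                rates.append(k if ok else None)
                fit_pars.append((A, C, rmse) if ok else None)
        if not scores:
            logger.warning("code %s produced no scores", code)
            continue
        pid = code_to_peptide.get(code, str(code)) if code_to_peptide else str(code)
        res = aggregate_replicates(pid, enzyme, scores, rates)
        ok_pars = [p for p in fit_pars if p is not None]
        rows.append(
            {
                "peptide_id": res.peptide_id,
                "enzyme": enzyme,
                "score_mean": res.score_mean,
                "score_sd": res.score_sd,
                "n_replicates": len(scores),
                "k": res.rate_k if res.rate_k is not None else np.nan,
                "k_sd": res.rate_k_sd if res.rate_k_sd is not None else np.nan,
                "A": float(np.mean([p[0] for p in ok_pars])) if ok_pars else np.nan,
                "C": float(np.mean([p[1] for p in ok_pars])) if ok_pars else np.nan,
                "rmse": float(np.mean([p[2] for p in ok_pars])) if ok_pars else np.nan,
                "fit_ok": bool(ok_pars),
                "negative_score_flag": bool(min(scores) < 0),
            }
        )
    return pd.DataFrame(rows)


def differential_matrix(results_a: pd.DataFrame, results_b: pd.DataFrame) -> pd.DataFrame:
    """Per-peptide score difference between two enzymes (A - B).

    Operates on the intersection of peptide ids; dropped ids are logged.
    """
    a = results_a.set_index("peptide_id")["score_mean"]
    b = results_b.set_index("peptide_id")["score_mean"]
    shared = a.index.intersection(b.index)
    if shared.empty:
        raise InputError("no shared peptides between the two result sets")
    dropped = set(a.index).symmetric_difference(b.index)
    if dropped:
        logger.info("differential_matrix: dropping %d unshared peptides", len(dropped))
    out = pd.DataFrame(
        {
            "peptide_id": shared,
            "score_a": a.loc[shared].to_numpy(),
            "score_b": b.loc[shared].to_numpy(),
        }
    )
    out["delta"] = out["score_a"] - out["score_b"]
    return out.reset_index(drop=True)


def group_scores(results: pd.DataFrame, library, by: str = "acceptor") -> pd.DataFrame:
    """Group per-peptide scores by a library design attribute.

    ``by`` is "acceptor" (pS vs pT) or "plus1_pro" (+1 proline vs other).
    ``library`` is a list of :class:`~beadphos.library_design.PhosphoPeptide`.
    """
    attr = {}
    for p in library:
        if by == "acceptor":
            attr[p.peptide_id] = p.acceptor
        elif by == "plus1_pro":
            attr[p.peptide_id] = "plus1_P" if p.plus1_residue == "P" else "plus1_other"
        else:
            raise InputError(f"unknown grouping attribute {by!r}")
    df = results.copy()
    df["group"] = df["peptide_id"].map(attr)
    df = df.dropna(subset=["group"])
    return (
        df.groupby("group")["score_mean"]
        .agg(n="count", mean="mean", sd=lambda v: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0)
        .reset_index()
    )
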