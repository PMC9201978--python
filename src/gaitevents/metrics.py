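"""Validation metrics for gait-event detection and stride parameters.

Event level: detections are matched one-to-one to reference events
inside a tolerance window (TW, default 0.5 s centred on the reference),
yielding true positives (TP), false negatives (FN) and false positives
(FP); from these sensitivity S = TP/(TP+FN), positive predictive value
PPV = TP/(TP+FP) and the F1 harmonic mean are computed.  Timing errors
dt = detected - reference (negative = anticipation) are summarised by
the median error (ME, bias), inter-quartile range error (IQRE,
precision) and median absolute error (MAE, accuracy).

Stride level: errors are computed only for strides whose bounding ICs
are both true positives; absolute agreement between detected and
reference stride parameters is quantified by ICC(2,1) (absolute
agreement, two-way model, single measure) with its 95% confidence
interval, Spearman rank correlation, Bland-Altman bias and limits of
agreement, and RMSE.

Quantiles use linear interpolation between order statistics throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_TW = 0.5  # tolerance window, seconds

STRIDE_PARAMS = ("duration", "length", "speed", "stance", "swing")


# ----------------------------------------------------------------------
# event matching
# ----------------------------------------------------------------------

@dataclass
class MatchResult:
    """One-to-one matching of detected to reference events."""

    pairs: list[tuple[float, float]]   # (reference time, detected time)
    fn_times: list[float]
    fp_times: list[float]
    tw: float

    @property
    def tp(self) -> int:
        return len(self.pairs)

    @property
    def fn(self) -> int:
        return len(self.fn_times)

    @property
    def fp(self) -> int:
        return len(self.fp_times)

    @property
    def errors(self) -> np.ndarray:
        """dt = detected - reference for each pair (seconds)."""
        return np.array([d - r for r, d in self.pairs], dtype=float)


def match_events(detected: np.ndarray, reference: np.ndarray,
                 tw: float = DEFAULT_TW,
                 reference_excluded: np.ndarray | None = None) -> MatchResult:
    """Greedy nearest-neighbour one-to-one matching.

    Reference events are processed in time order; each is paired with the
    nearest unmatched detection within +-tw/2 (ties resolved toward the
    earlier detection).  ``reference_excluded`` marks reference events
    whose detection was impossible (marker occlusion); they are removed
    before matching rather than counted as misses.
    """
    detected = np.sort(np.asarray(detected, dtype=float))
    reference = np.sort(np.asarray(reference, dtype=float))
    if reference_excluded is not None and len(reference_excluded):
        excl = np.asarray(reference_excluded, dtype=float)
        keep = ~np.isin(reference, excl)
        reference = reference[keep]
    half = tw / 2.0
    used = np.zeros(detected.size, dtype=bool)
    pairs: list[tuple[float, float]] = []
    fn: list[float] = []
    for r in reference:
        cand = np.flatnonzero(~used & (np.abs(detected - r) <= half + 1e-12))
        if cand.size == 0:
            fn.append(float(r))
            continue
        d = np.abs(detected[cand] - r)
        j = cand[np.argmin(d)]  # argmin returns the first (earlier) on ties
        used[j] = True
        pairs.append((float(r), float(detected[j])))
    fp = [float(t) for t in detected[~used]]
    return MatchResult(pairs=pairs, fn_times=fn, fp_times=fp, tw=tw)


def classification_scores(match: MatchResult | tuple[int, int, int]
                          ) -> tuple[float | None, float | None, float | None]:
    """(S, PPV, F1).  Undefined ratios are returned as None; F1 is 0 when
    S and PPV are both zero, and None when either is undefined."""
    if isinstance(match, MatchResult):
        tp, fn, fp = match.tp, match.fn, match.fp
    else:
        tp, fn, fp = match
    s = tp / (tp + fn) if (tp + fn) > 0 else None
    ppv = tp / (tp + fp) if (tp + fp) > 0 else None
    if s is None or ppv is None:
        f1 = None
    elif s + ppv == 0:
        f1 = 0.0
    else:
        f1 = 2.0 * ppv * s / (ppv + s)
    return s, ppv, f1


# ----------------------------------------------------------------------
# timing errors
# ----------------------------------------------------------------------

def timing_error_stats(errors: np.ndarray) -> tuple[float, float, float]:
    """(ME, IQRE, MAE): median error, inter-quartile-range error and
    median absolute error of a timing-error sample."""
    errors = np.asarray(errors, dtype=float)
    if errors.size == 0:
        raise ValueError("timing_error_stats requires at least one error")
    me = float(np.median(errors))
    q1, q3 = np.quantile(errors, [0.25, 0.75])
    mae = float(np.median(np.abs(errors)))
    return me, float(q3 - q1), mae


def impute_fn_errors(errors: np.ndarray, n_fn: int,
                     pool: np.ndarray) -> np.ndarray:
    """Augment a timing-error sample with imputed false-negative errors.

    When more than 5% of the expected events are missing, each FN is
    assigned the method's largest observed error (maximum magnitude, with
    its sign); otherwise the mean observed error.  False positives never
    enter the error statistics.
    """
    errors = np.asarray(errors, dtype=float)
    pool = np.asarray(pool, dtype=float)
    if n_fn == 0:
        return errors
    if pool.size == 0:
        raise ValueError("cannot impute FN errors from an empty pool")
    missing_frac = n_fn / (n_fn + errors.size)
    if missing_frac > 0.05:
        value = pool[np.argmax(np.abs(pool))]
    else:
        value = np.mean(pool)
    return np.concatenate([errors, np.full(n_fn, value)])


# ----------------------------------------------------------------------
# performance report (event level)
# ----------------------------------------------------------------------

@dataclass
class PerformanceReport:
    """Event-level scores for one (method, condition, event type) stratum."""

    method: str
    condition: str
    event_type: str
    n_reference: int
    tp: int
    fn: int
    fp: int
    sensitivity: float | None
    ppv: float | None
    f1: float | None
    me_s: float | None
    iqre_s: float | None
    mae_s: float | None
    resolution_s: float
    frac_within_resolution: float | None

    def as_dict(self) -> dict:
        return {
            "method": self.method, "condition": self.condition,
            "event_type": self.event_type, "n_reference": self.n_reference,
            "TP": self.tp, "FN": self.fn, "FP": self.fp,
            "S": self.sensitivity, "PPV": self.ppv, "F1": self.f1,
            "ME_s": self.me_s, "IQRE_s": self.iqre_s, "MAE_s": self.mae_s,
            "resolution_s": self.resolution_s,
            "frac_within_resolution": self.frac_within_resolution,
        }


def evaluate_events(detected, reference, sampling_rate: float,
                    tw: float = DEFAULT_TW, method: str = "",
                    conditions: tuple[str, ...] = ("SW", "CW", "SN"),
                    impute_fn: bool = False) -> list[PerformanceReport]:
    """Stratified event-level evaluation.

    ``detected`` and ``reference`` are GaitEventSet-like objects (or two
    equal-length lists of them, pooled as one sample — e.g. the trials of
    a validation corpus); matching is done per (side, event type) and the
    resulting pairs/misses are stratified by the reference event's
    condition label (false positives by the detected event's own label).
    """
    if not isinstance(detected, (list, tuple)):
        detected, reference = [detected], [reference]
    resolution = 1.0 / sampling_rate
    reports: list[PerformanceReport] = []
    for typ in ("IC", "FC"):
        rows = {c: {"tp": 0, "fn": 0, "fp": 0, "errors": []} for c in conditions}
        for det_set, ref_set in zip(detected, reference):
            for side in ("L", "R"):
                det = list(det_set.select(side, typ))
                ref = list(ref_set.select(side, typ))
                m = match_events(np.array([e.time for e in det]),
                                 np.array([e.time for e in ref]), tw)
                cond_of_ref = {e.time: (e.condition if e.condition in conditions
                                        else "SW") for e in ref}
                cond_of_det = {e.time: (e.condition if e.condition in conditions
                                        else "SW") for e in det}
                for r, d in m.pairs:
                    c = cond_of_ref[r]
                    rows[c]["tp"] += 1
                    rows[c]["errors"].append(d - r)
                for r in m.fn_times:
                    rows[cond_of_ref[r]]["fn"] += 1
                for d in m.fp_times:
                    rows[cond_of_det[d]]["fp"] += 1
        for c in conditions:
            row = rows[c]
            errors = np.array(row["errors"], dtype=float)
            if impute_fn and row["fn"] and errors.size:
                pool = np.concatenate(
                    [rows[cc]["errors"] for cc in conditions
                     if rows[cc]["errors"]]) if any(
                        rows[cc]["errors"] for cc in conditions) else errors
                errors = impute_fn_errors(errors, row["fn"], pool)
            s, ppv, f1 = classification_scores((row["tp"], row["fn"], row["fp"]))
            if errors.size:
                me, iqre, mae = timing_error_stats(errors)
                frac = float(np.mean(np.abs(errors) <= resolution + 1e-12))
            else:
                me = iqre = mae = frac = None
            reports.append(PerformanceReport(
                method=method, condition=c, event_type=typ,
                n_reference=row["tp"] + row["fn"], tp=row["tp"], fn=row["fn"],
                fp=row["fp"], sensitivity=s, ppv=ppv, f1=f1,
                me_s=me, iqre_s=iqre, mae_s=mae, resolution_s=resolution,
                frac_within_resolution=frac))
    return reports


# ----------------------------------------------------------------------
# stride-parameter error propagation
# ----------------------------------------------------------------------

def stride_param_errors(detected: pd.DataFrame, reference: pd.DataFrame,
                        tw: float = DEFAULT_TW,
                        temporal_resolution: float = 0.01,
                        spatial_resolution: float = 0.002,
                        speed_resolution: float = 0.01) -> pd.DataFrame:
    """Paired per-stride errors for strides identified by TP initial contacts.

    Both tables follow the stride-table layout.  A reference stride is
    paired when both of its bounding ICs match a detected IC (within
    +-tw/2) and those detections bound one detected stride; remaining
    reference strides are counted missing (column ``matched`` False, error
    columns NaN).  Errors are detected - reference, absolute and relative
    (percent of the reference value).
    """
    rows = []
    for side in ("L", "R"):
        det = detected[detected["side"] == side]
        ref = reference[reference["side"] == side]
        det_ics = np.unique(np.concatenate([det["t_ic_start"].to_numpy(float),
                                            det["t_ic_end"].to_numpy(float)])) \
            if len(det) else np.array([])
        det_by_start = {round(t, 9): i for i, t in
                        zip(det.index, det["t_ic_start"])}
        m = match_events(det_ics,
                         np.unique(np.concatenate(
                             [ref["t_ic_start"].to_numpy(float),
                              ref["t_ic_end"].to_numpy(float)]))
                         if len(ref) else np.array([]), tw)
        ref_to_det = {r: d for r, d in m.pairs}
        for _, r in ref.iterrows():
            d_start = ref_to_det.get(r["t_ic_start"])
            d_end = ref_to_det.get(r["t_ic_end"])
            row = {"side": side, "condition": r["condition"],
                   "t_ic_start_ref": r["t_ic_start"], "matched": False}
            i = det_by_start.get(round(d_start, 9)) if d_start is not None else None
            if i is not None and d_end is not None and \
                    abs(detected.loc[i, "t_ic_end"] - d_end) < 1e-9:
                d = detected.loc[i]
                row["matched"] = True
                values = {
                    "duration": (d["duration_s"], r["duration_s"]),
                    "length": (d["length_m"], r["length_m"]),
                    "speed": (d["speed_mps"], r["speed_mps"]),
                    "stance": (d["stance_s"], r["stance_s"]),
                    "swing": (d["swing_s"], r["swing_s"]),
                }
                for name, (dv, rv) in values.items():
                    if dv is None or rv is None or not np.isfinite([dv, rv]).all():
                        row[f"{name}_err"] = np.nan
                        row[f"{name}_rel_err_pct"] = np.nan
                        row[f"{name}_det"] = np.nan
                        row[f"{name}_ref"] = np.nan
                        continue
                    row[f"{name}_det"] = dv
                    row[f"{name}_ref"] = rv
                    row[f"{name}_err"] = dv - rv
                    row[f"{name}_rel_err_pct"] = (100.0 * (dv - rv) / rv
                                                  if rv != 0 else np.nan)
            rows.append(row)
    table = pd.DataFrame(rows)
    table.attrs["resolutions"] = {
        "duration": temporal_resolution, "stance": temporal_resolution,
        "swing": temporal_resolution, "length": spatial_resolution,
        "speed": speed_resolution,
    }
    return table


def summarize_stride_errors(table: pd.DataFrame) -> pd.DataFrame:
    """ME/IQRE/MAE (absolute and relative) per parameter, plus the fraction
    of matched strides with |error| within the measurement resolution."""
    res = table.attrs.get("resolutions", {})
    out = []
    matched = table[table["matched"]] if len(table) else table
    for name in STRIDE_PARAMS:
        col = f"{name}_err"
        if col not in matched or matched[col].dropna().empty:
            continue
        err = matched[col].dropna().to_numpy(float)
        rel = matched[f"{name}_rel_err_pct"].dropna().to_numpy(float)
        me, iqre, mae = timing_error_stats(err)
        row = {"parameter": name, "n": err.size, "ME": me, "IQRE": iqre, "MAE": mae}
        if rel.size:
            rme, riqre, rmae = timing_error_stats(rel)
            row.update({"ME_pct": rme, "IQRE_pct": riqre, "MAE_pct": rmae})
        r = res.get(name)
        if r is not None:
            row["frac_within_resolution"] = float(np.mean(np.abs(err) <= r + 1e-12))
        out.append(row)
    summary = pd.DataFrame(out)
    if len(table):
        summary.attrs["missing_strides"] = int((~table["matched"]).sum())
        summary.attrs["n_reference_strides"] = int(len(table))
    return summary


# ----------------------------------------------------------------------
# agreement statistics
# ----------------------------------------------------------------------

@dataclass
class AgreementReport:
    """Paired-sample agreement between detected and reference values."""

    n: int
    icc21: float | None
    icc21_ci95: tuple[float, float] | None
    spearman_rho: float | None
    bias: float
    loa: tuple[float, float]
    rmse: float
    ba_mean: np.ndarray = field(repr=False, default=None)
    ba_diff: np.ndarray = field(repr=False, default=None)


def icc21(data: np.ndarray, alpha: float = 0.05
          ) -> tuple[float, tuple[float, float]]:
    """ICC(2,1): single-measure, absolute-agreement intraclass correlation
    from the two-way ANOVA mean squares, with the F-based 95% CI.

    ``data`` is an (n subjects x k raters) matrix.
    """
    data = np.asarray(data, dtype=float)
    n, k = data.shape
    if n < 3 or k < 2:
        raise ValueError("ICC requires at least 3 subjects and 2 raters")
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        raise ZeroDivisionError("zero variance in both raters: ICC undefined")
    icc = (msr - mse) / denom
    # McGraw & Wong confidence interval for ICC(A,1)
    a = k * icc / (n * (1 - icc)) if icc < 1 else np.inf
    b = 1 + k * icc * (n - 1) / (n * (1 - icc)) if icc < 1 else np.inf
    if np.isfinite(a) and (a * msc + b * mse) > 0:
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1)))
        f1 = stats.f.ppf(1 - alpha / 2, n - 1, v)
        f2 = stats.f.ppf(1 - alpha / 2, v, n - 1)
        lower = n * (msr - f1 * mse) / (
            f1 * (k * msc + (k * n - k - n) * mse) + n * msr)
        upper = n * (f2 * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f2 * msr)
    else:
        lower = upper = 1.0
    return float(icc), (float(lower), float(upper))


def agreement_stats(detected: np.ndarray, reference: np.ndarray) -> AgreementReport:
    """Absolute/relative agreement between paired parameter estimates:
    ICC(2,1) with 95% CI, Spearman rho, Bland-Altman bias and limits of
    agreement (bias +- 1.96 SD of the differences), and RMSE."""
    detected = np.asarray(detected, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if detected.shape != reference.shape or detected.size < 3:
        raise ValueError("agreement_stats requires >= 3 paired values")
    d = detected - reference
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    loa = (bias - 1.96 * sd, bias + 1.96 * sd)
    rmse = float(np.sqrt(np.mean(d ** 2)))
    data = np.column_stack([reference, detected])
    try:
        icc, ci = icc21(data)
    except ZeroDivisionError:
        icc, ci = None, None
    if np.ptp(detected) == 0 or np.ptp(reference) == 0:
        rho = None
    else:
        rho = float(stats.spearmanr(detected, reference).statistic)
    return AgreementReport(
        n=detected.size, icc21=icc, icc21_ci95=ci, spearman_rho=rho,
        bias=bias, loa=loa, rmse=rmse,
        ba_mean=0.5 * (detected + reference), ba_diff=d)
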