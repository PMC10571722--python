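"""Survival machinery: Cox partial-likelihood loss, C-index, KM, log-rank.

The training objective is the negative Cox log partial likelihood

    loss(r) = sum_i  mu_i * ( -r_i + log sum_{j : t_j >= t_i} exp(r_j) )

where ``r`` are model risks, ``t`` observed times and ``mu`` event indicators
(1 = death, 0 = censored).  Tied event times are handled with Breslow's
approximation — each event's risk set simply includes every subject whose
time is >= its own — which is the convention for deep Cox objectives.  The
log-sum-exp is computed with max-shift stabilization, and the analytic
gradient is provided for the numpy training loop.

Discrimination is measured with the concordance index.  The model emits one
time-constant scalar risk per patient, so Antolini's time-dependent estimator
reduces to pairwise concordance: the fraction of comparable pairs
(t_i < t_j, mu_i = 1) in which the earlier-event patient got the higher risk,
with half credit for risk ties.  Group survival is summarized with the
Kaplan-Meier product-limit estimator and compared with the two-sided
log-rank test; risk stratification picks the cutoff on a quantile grid that
maximizes the log-rank statistic on the training cohort.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

DEFAULT_QUANTILE_GRID = tuple(np.round(np.arange(0.25, 0.751, 0.05), 2))


@dataclass(frozen=True)
class SurvivalRecord:
    """One patient's outcome: observed time and event indicator.

    ``event`` is 1 for death, 0 for censoring (the patient left observation
    alive, so true survival exceeds ``time``).
    """

    patient_id: str
    time: float
    event: int
    time_unit: str = "years"

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ValueError(f"survival time must be positive, got {self.time}")
        if self.event not in (0, 1):
            raise ValueError(f"event must be 0 or 1, got {self.event}")


def records_to_arrays(records) -> tuple[np.ndarray, np.ndarray]:
    """(times, events) arrays from a sequence of SurvivalRecord."""
    t = np.array([r.time for r in records], dtype=np.float64)
    e = np.array([r.event for r in records], dtype=np.float64)
    return t, e


class UndefinedResultError(ValueError):
    """Raised when a statistic has no informative value (e.g. no events)."""


def _as_arrays(risks, times, events):
    r = np.asarray(risks, dtype=np.float64).ravel()
    t = np.asarray(times, dtype=np.float64).ravel()
    e = np.asarray(events, dtype=np.float64).ravel()
    if not (len(r) == len(t) == len(e)):
        raise ValueError(f"length mismatch: risks {len(r)}, times {len(t)}, events {len(e)}")
    if len(r) == 0:
        raise ValueError("empty inputs")
    if not np.isin(e, (0.0, 1.0)).all():
        raise ValueError("events must be binary 0/1")
    return r, t, e


def cox_loss(risks, times, events) -> float:
    """Negative Cox log partial likelihood (Breslow ties, sum over events)."""
    loss, _ = cox_loss_and_grad(risks, times, events)
    return loss


def cox_loss_and_grad(risks, times, events) -> tuple[float, np.ndarray]:
    """Loss and its gradient with respect to the risk vector.

    d loss / d r_k = -mu_k + sum_{i : events} mu_i * 1[t_k >= t_i]
                     * exp(r_k) / sum_{j : t_j >= t_i} exp(r_j)
    """
    r, t, e = _as_arrays(risks, times, events)
    if e.sum() == 0:
        warnings.warn("no events: Cox partial likelihood has no informative terms")
        return 0.0, np.zeros_like(r)
    # at_risk[i, j] = 1 if subject j is in the risk set of subject i's time
    at_risk = t[None, :] >= t[:, None]
    shift = r.max()
    exp_r = np.exp(r - shift)
    denom = at_risk @ exp_r  # sum_{j: t_j >= t_i} exp(r_j - shift)
    log_denom = np.log(denom) + shift
    loss = float(np.sum(e * (-r + log_denom)))
    # gradient: softmax weights of each risk set, summed over event rows
    weights = (e / denom) @ at_risk  # sum_i e_i * at_risk[i, k] / denom_i
    grad = -e + exp_r * weights
    return loss, grad


def concordance_index(risks, times, events) -> float:
    """Pairwise concordance with half credit for tied risks.

    Comparable pairs are (i, j) with t_i < t_j and mu_i = 1; the pair is
    concordant when r_i > r_j.  With one time-constant risk per subject this
    coincides with Antolini's estimator.
    """
    r, t, e = _as_arrays(risks, times, events)
    if not np.isfinite(r).all():
        raise ValueError("risks must be finite")
    comparable = (t[:, None] < t[None, :]) & (e[:, None] == 1)
    n_pairs = int(comparable.sum())
    if n_pairs == 0:
        raise UndefinedResultError("no comparable pairs")
    diff = r[:, None] - r[None, :]
    concordant = float(((diff > 0) & comparable).sum())
    tied = float(((diff == 0) & comparable).sum())
    return (concordant + 0.5 * tied) / n_pairs


@dataclass
class KMCurve:
    """Product-limit survival estimate, defined stepwise.

    ``survival_probs[k]`` is S(t) for t in [event_times[k], event_times[k+1]);
    S = 1 before the first event time.
    """

    event_times: np.ndarray
    survival_probs: np.ndarray
    n_at_risk: np.ndarray
    n_events: np.ndarray

    def evaluate(self, t: float) -> float:
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival_probs[idx])


def km_estimate(times, events) -> KMCurve:
    """Kaplan-Meier estimator over the distinct event times."""
    t = np.asarray(times, dtype=np.float64).ravel()
    e = np.asarray(events, dtype=np.float64).ravel()
    if len(t) == 0:
        raise ValueError("empty inputs")
    event_times = np.unique(t[e == 1])
    probs, at_risk, d_events = [], [], []
    s = 1.0
    for et in event_times:
        n = int((t >= et).sum())
        d = int(((t == et) & (e == 1)).sum())
        s *= 1.0 - d / n
        probs.append(s)
        at_risk.append(n)
        d_events.append(d)
    return KMCurve(
        event_times=event_times,
        survival_probs=np.asarray(probs),
        n_at_risk=np.asarray(at_risk),
        n_events=np.asarray(d_events),
    )


def logrank_test(times_a, events_a, times_b, events_b) -> tuple[float, float]:
    """Two-sided log-rank test; returns (chi2, p) against chi-square(1).

    Uses the standard observed-minus-expected statistic with hypergeometric
    variance at each distinct event time.
    """
    ta = np.asarray(times_a, dtype=np.float64).ravel()
    ea = np.asarray(events_a, dtype=np.float64).ravel()
    tb = np.asarray(times_b, dtype=np.float64).ravel()
    eb = np.asarray(events_b, dtype=np.float64).ravel()
    if len(ta) == 0 or len(tb) == 0:
        raise ValueError("both groups must be nonempty")
    t_all = np.concatenate([ta, tb])
    e_all = np.concatenate([ea, eb])
    if e_all.sum() == 0:
        raise UndefinedResultError("no events in either group")
    o_minus_e = 0.0
    var = 0.0
    for et in np.unique(t_all[e_all == 1]):
        n1 = int((ta >= et).sum())
        n2 = int((tb >= et).sum())
        n = n1 + n2
        d = int(((t_all == et) & (e_all == 1)).sum())
        d1 = int(((ta == et) & (ea == 1)).sum())
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    if var == 0.0:
        return 0.0, 1.0
    chi2 = o_minus_e**2 / var
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p


@dataclass
class StratificationResult:
    """Low/high risk dichotomization with its log-rank comparison."""

    cutoff: float
    labels: np.ndarray  # "low" / "high" per patient
    logrank_chi2: float
    p_value: float

    @property
    def group_sizes(self) -> dict[str, int]:
        return {
            "low": int((self.labels == "low").sum()),
            "high": int((self.labels == "high").sum()),
        }


def stratify(risks, cutoff: float, times=None, events=None) -> StratificationResult:
    """Split into low (risk <= cutoff) and high (risk > cutoff) groups.

    Boundary ties go to the low-risk group (strict inequality for high).
    If survival data are supplied, the induced groups' log-rank chi2/p are
    attached; a degenerate split (one group empty) warns and reports the
    p = 1 sentinel.
    """
    r = np.asarray(risks, dtype=np.float64).ravel()
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    labels = np.where(r > cutoff, "high", "low")
    chi2, p = 0.0, 1.0
    high = labels == "high"
    if high.all() or (~high).all():
        warnings.warn("stratification produced an empty group; p = 1 sentinel")
    elif times is not None and events is not None:
        t = np.asarray(times, dtype=np.float64).ravel()
        e = np.asarray(events, dtype=np.float64).ravel()
        try:
            chi2, p = logrank_test(t[~high], e[~high], t[high], e[high])
        except UndefinedResultError:
            warnings.warn("no events in stratified groups; p = 1 sentinel")
    return StratificationResult(cutoff=float(cutoff), labels=labels, logrank_chi2=chi2, p_value=p)


def export_stratification(
    strat: StratificationResult,
    times,
    events,
    out_prefix,
) -> None:
    """Write the stratified KM curves as CSV and a step plot (PNG).

    Produces ``<prefix>_km.csv`` (group, time, survival) and
    ``<prefix>_km.png``.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import pandas as pd
    from pathlib import Path

    t = np.asarray(times, dtype=np.float64).ravel()
    e = np.asarray(events, dtype=np.float64).ravel()
    prefix = Path(out_prefix)
    rows = []
    fig, ax = plt.subplots(figsize=(5, 4))
    for label, color in (("low", "tab:blue"), ("high", "tab:red")):
        mask = strat.labels == label
        if not mask.any():
            continue
        curve = km_estimate(t[mask], e[mask])
        steps_t = np.concatenate([[0.0], curve.event_times])
        steps_s = np.concatenate([[1.0], curve.survival_probs])
        ax.step(steps_t, steps_s, where="post", label=f"{label} risk (n={mask.sum()})", color=color)
        rows += [
            {"group": label, "time": float(tt), "survival": float(ss_)}
            for tt, ss_ in zip(steps_t, steps_s)
        ]
    ax.set_xlabel("time")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.legend()
    ax.set_title(f"log-rank chi2 = {strat.logrank_chi2:.2f}, p = {strat.p_value:.2e}")
    fig.tight_layout()
    fig.savefig(prefix.with_name(prefix.name + "_km.png"), dpi=120)
    plt.close(fig)
    pd.DataFrame(rows).to_csv(prefix.with_name(prefix.name + "_km.csv"), index=False)


def optimal_quantile_cutoff(
    risks, times, events, quantile_grid=DEFAULT_QUANTILE_GRID
) -> float:
    """Risk cutoff at the grid quantile maximizing the log-rank statistic.

    Evaluated on the provided (training) cohort.  Candidates that leave one
    group empty are infeasible; chi2 ties break toward the quantile nearest
    the median.
    """
    r, t, e = _as_arrays(risks, times, events)
    grid = np.asarray(quantile_grid, dtype=np.float64).ravel()
    if len(grid) == 0 or ((grid <= 0) | (grid >= 1)).any():
        raise ValueError("quantile grid must lie strictly inside (0, 1)")
    best: tuple[float, float, float] | None = None  # (chi2, -|q - .5|, cutoff)
    for q in sorted(grid):
        cutoff = float(np.quantile(r, q))
        high = r > cutoff
        if high.all() or (~high).all():
            continue
        chi2, _ = logrank_test(t[~high], e[~high], t[high], e[high])
        key = (chi2, -abs(q - 0.5), cutoff)
        if best is None or key[:2] > best[:2]:
            best = key
    if best is None:
        raise ValueError("no feasible cutoff candidate in the quantile grid")
    return best[2]
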