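"""Independent oracles used by the test suite.

Each function here is a deliberately naive, loop-based implementation kept
separate from the package code paths it checks.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def brute_force_pair_matrix(expr: pd.DataFrame, genes: list[str]):
    """Double-loop pair indicator construction."""
    rows = {}
    pairs = []
    for i, a in enumerate(genes):
        for b in genes[i + 1:]:
            pairs.append((a, b))
            rows[f"{a}|{b}"] = [
                1 if expr.loc[a, s] > expr.loc[b, s] else 0 for s in expr.columns
            ]
    return pd.DataFrame.from_dict(rows, orient="index", columns=expr.columns), pairs


def km_oracle(time, event):
    """Direct product-limit computation; returns {event_time: S(t)}."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    s = 1.0
    out = {}
    for tau in sorted(set(time[event == 1])):
        n_at_risk = int((time >= tau).sum())
        d = int(((time == tau) & (event == 1)).sum())
        s *= 1.0 - d / n_at_risk
        out[tau] = s
    return out


def logrank_2group_oracle(time, event, group):
    """Observed-minus-expected log-rank chi-square for two groups."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    group = np.asarray(group)
    g1 = group == np.unique(group)[0]
    U = 0.0
    V = 0.0
    for tau in sorted(set(time[event == 1])):
        at_risk = time >= tau
        n = int(at_risk.sum())
        n1 = int((at_risk & g1).sum())
        d = int(((time == tau) & (event == 1)).sum())
        d1 = int(((time == tau) & (event == 1) & g1).sum())
        U += d1 - d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return U * U / V if V > 0 else 0.0


def mann_whitney_auc(case_scores, control_scores):
    """Pairwise-comparison AUC with ties counted 1/2."""
    total = 0.0
    for a in case_scores:
        for b in control_scores:
            total += (a > b) + 0.5 * (a == b)
    return total / (len(case_scores) * len(control_scores))


def ipcw_auc_oracle(scores, time, event, horizon):
    """Weighted pairwise IPCW AUC: direct double sum over cases/controls,
    with marginal KM censoring weights evaluated just before event times."""
    scores = np.asarray(scores, float)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    # censoring KM (censoring as the event)
    g = 1.0
    gmap = []  # (time, G just after that time)
    for tau in sorted(set(time)):
        at_risk = int((time >= tau).sum())
        dc = int(((time == tau) & (event == 0)).sum())
        g *= 1.0 - dc / at_risk
        gmap.append((tau, g))

    def g_left(t):
        val = 1.0
        for tau, gv in gmap:
            if tau < t:
                val = gv
            else:
                break
        return val

    cases = np.where((time <= horizon) & (event == 1))[0]
    controls = np.where(time > horizon)[0]
    w = np.array([1.0 / g_left(time[i]) for i in cases])
    num = 0.0
    for wi, i in zip(w, cases):
        for j in controls:
            num += wi * ((scores[i] > scores[j]) + 0.5 * (scores[i] == scores[j]))
    return num / (w.sum() * len(controls))


def spearman_oracle(x, y):
    """Pearson correlation of average ranks, computed from first principles."""
    def avg_ranks(v):
        v = np.asarray(v, float)
        order = np.argsort(v, kind="mergesort")
        ranks = np.empty(len(v))
        i = 0
        sorted_v = v[order]
        while i < len(v):
            j = i
            while j < len(v) and sorted_v[j] == sorted_v[i]:
                j += 1
            ranks[order[i:j]] = (i + j - 1) / 2.0 + 1.0
            i = j
        return ranks

    rx, ry = avg_ranks(x), avg_ranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))


def chi_square_oracle(table: np.ndarray):
    """Textbook sum((O-E)^2 / E) without continuity correction."""
    table = np.asarray(table, float)
    total = table.sum()
    chi2 = 0.0
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            e = table[i].sum() * table[:, j].sum() / total
            chi2 += (table[i, j] - e) ** 2 / e
    return chi2


def random_survival(rng, n, censor_scale=None):
    """Simple exponential survival frame for evaluation tests."""
    t = rng.exponential(100.0, n) + 0.5
    if censor_scale is None:
        time, event = t, np.ones(n, int)
    else:
        c = rng.exponential(censor_scale, n) + 0.5
        time = np.minimum(t, c)
        event = (t <= c).astype(int)
    return pd.DataFrame(
        {"sample_id": [f"S{i:04d}" for i in range(n)], "time": time, "event": event}
    )
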