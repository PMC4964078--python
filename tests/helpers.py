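"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive — explicit loops and closed forms kept
free of the library code paths they validate.
"""

from __future__ import annotations

import numpy as np


def brute_concordance(time, event, risk) -> float:
    """Pairwise Harrell's C: earlier member of a comparable pair has an event;
    higher risk for the earlier event scores 1, ties in risk score 0.5."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    risk = np.asarray(risk, float)
    num = den = 0.0
    n = len(time)
    for i in range(n):
        for j in range(n):
            if i == j or time[i] >= time[j]:
                continue
            if event[i] != 1:
                continue
            den += 1.0
            if risk[i] > risk[j]:
                num += 1.0
            elif risk[i] == risk[j]:
                num += 0.5
    if den == 0:
        raise ValueError("no comparable pairs")
    return num / den


def cox_loglik(beta, time, event, x) -> float:
    """Cox log partial likelihood for one covariate, distinct event times."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    x = np.asarray(x, float)
    ll = 0.0
    for i in np.flatnonzero(event == 1):
        at_risk = time >= time[i]
        ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[at_risk])))
    return ll


def grid_max_cox_beta(time, event, x, lo=-6.0, hi=6.0) -> float:
    """Maximize the partial likelihood by two-stage grid search (1e-4 grid)."""
    grid = np.linspace(lo, hi, 2401)
    lls = [cox_loglik(b, time, event, x) for b in grid]
    b0 = grid[int(np.argmax(lls))]
    fine = np.linspace(b0 - 0.01, b0 + 0.01, 201)
    lls = [cox_loglik(b, time, event, x) for b in fine]
    return float(fine[int(np.argmax(lls))])


def km_product_limit(time, event):
    """Product-limit estimate at each distinct event time: Pi(1 - d_i/n_i)."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    grid = sorted(set(time[event == 1]))
    surv, s = [], 1.0
    for t in grid:
        n_at_risk = int(np.sum(time >= t))
        d = int(np.sum((time == t) & (event == 1)))
        s *= 1.0 - d / n_at_risk
        surv.append(s)
    return np.array(grid), np.array(surv)


def spearman_formula(x, y) -> float:
    """1 - 6*sum(d^2)/(n(n^2-1)); valid for distinct values only."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    rx = np.argsort(np.argsort(x)) + 1
    ry = np.argsort(np.argsort(y)) + 1
    d = rx - ry
    return 1.0 - 6.0 * float(np.sum(d**2)) / (n * (n**2 - 1))


def step_running_sum(ordered_symbols, metric_by_symbol, members, p=1.0):
    """Step-by-step weighted KS running sum; returns (running, signed max dev)."""
    hits = [s in set(members) for s in ordered_symbols]
    n = len(ordered_symbols)
    n_h = sum(hits)
    denom_hits = sum(abs(metric_by_symbol[s]) ** p for s, h in zip(ordered_symbols, hits) if h)
    running, total = [], 0.0
    for s, h in zip(ordered_symbols, hits):
        if h:
            if denom_hits > 0:
                total += abs(metric_by_symbol[s]) ** p / denom_hits
            else:
                total += 1.0 / n_h
        else:
            total -= 1.0 / (n - n_h)
        running.append(total)
    running = np.array(running)
    return running, float(running[int(np.argmax(np.abs(running)))])


def nsc_by_hand(X, labels, delta):
    """From-scratch shrunken-centroid quantities for a small genes x samples
    array. Returns dict with d, d_shrunk, shrunken centroids, pooled sd, s0."""
    X = np.asarray(X, float)
    labels = np.asarray(labels)
    classes = list(dict.fromkeys(labels))
    n = X.shape[1]
    overall = X.mean(axis=1)
    out = {"classes": classes, "overall": overall}
    cents, ss = {}, np.zeros(X.shape[0])
    for k in classes:
        sub = X[:, labels == k]
        cents[k] = sub.mean(axis=1)
        ss += ((sub - cents[k][:, None]) ** 2).sum(axis=1)
    s = np.sqrt(ss / (n - len(classes)))
    s0 = float(np.median(s))
    out.update(pooled_sd=s, s0=s0, class_centroids=cents)
    d, d_shr, shrunk = {}, {}, {}
    for k in classes:
        nk = int(np.sum(labels == k))
        mk = np.sqrt(1.0 / nk - 1.0 / n)
        d[k] = (cents[k] - overall) / (mk * (s + s0))
        d_shr[k] = np.sign(d[k]) * np.maximum(np.abs(d[k]) - delta, 0.0)
        shrunk[k] = overall + mk * (s + s0) * d_shr[k]
    out.update(d=d, d_shrunk=d_shr, shrunken_centroids=shrunk)
    return out


def nsc_discriminant_by_hand(model_dict, x, priors):
    """Brute-force discriminant over surviving genes; returns dict class->score."""
    classes = model_dict["classes"]
    s = model_dict["pooled_sd"] + model_dict["s0"]
    surviving = np.zeros(len(s), dtype=bool)
    for k in classes:
        surviving |= np.abs(model_dict["d_shrunk"][k]) > 0
    scores = {}
    for k in classes:
        cent = model_dict["shrunken_centroids"][k]
        val = 0.0
        for g in np.flatnonzero(surviving):
            val += (x[g] - cent[g]) ** 2 / s[g] ** 2
        scores[k] = val - 2.0 * np.log(priors[k])
    return scores
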