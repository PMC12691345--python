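"""Independent brute-force oracles.

Naive, loop-based transcriptions of the loss formulas, metrics and the Welch
t-test, written without reference to the package implementations (no shared
helpers, no vectorisation) so agreement is a genuine dual-route check.
"""

import math

EPS = 1e-12


def oracle_target_profile(c, n):
    return [1.0 - abs(i - c) / (n - 1) for i in range(n)]


def oracle_ce(p, c):
    return -math.log(max(p[c], EPS))


def oracle_orl(p, c, signed=False):
    n = len(p)
    total = 0.0
    for i in range(n):
        o_i = 1.0 - abs(i - c) / (n - 1)
        d_i = p[i] - o_i
        arg = (1.0 - d_i) if signed else (1.0 - abs(d_i))
        total += -math.log(max(arg, EPS))
    return total


def oracle_ordl(p, c, lam=1.0):
    return oracle_ce(p, c) + lam * oracle_orl(p, c)


def oracle_cdw(p, c, a):
    total = 0.0
    for i in range(len(p)):
        if i == c:
            continue
        total += -math.log(max(1.0 - p[i], EPS)) * abs(i - c) ** a
    return total


def oracle_corn(task_logits, labels):
    """Per-pair BCE enumeration over chained conditional subsets."""
    n_tasks = len(task_logits[0])
    total, pairs = 0.0, 0
    for k in range(n_tasks):
        for z_row, c in zip(task_logits, labels):
            if c < k:  # not in task k's conditional subset {c >= k}
                continue
            z = z_row[k]
            q = 1.0 / (1.0 + math.exp(-z)) if z >= 0 else math.exp(z) / (1 + math.exp(z))
            y = 1.0 if c > k else 0.0
            total += -(y * math.log(max(q, EPS)) + (1 - y) * math.log(max(1 - q, EPS)))
            pairs += 1
    return total / pairs if pairs else 0.0


def oracle_metrics(truths, preds, n):
    """Accuracy / macro F1 / MAE / RMSE by direct enumeration."""
    m = len(truths)
    acc = sum(t == p for t, p in zip(truths, preds)) / m
    f1s = []
    for k in range(n):
        tp = sum(1 for t, p in zip(truths, preds) if t == k and p == k)
        fp = sum(1 for t, p in zip(truths, preds) if t != k and p == k)
        fn = sum(1 for t, p in zip(truths, preds) if t == k and p != k)
        f1s.append(2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0)
    mae = sum(abs(t - p) for t, p in zip(truths, preds)) / m
    rmse = math.sqrt(sum((t - p) ** 2 for t, p in zip(truths, preds)) / m)
    return acc, sum(f1s) / n, mae, rmse


def oracle_qwk(truths, preds, n):
    """Quadratic weighted kappa from the confusion matrix, by hand."""
    m = len(truths)
    obs = [[0.0] * n for _ in range(n)]
    for t, p in zip(truths, preds):
        obs[t][p] += 1.0 / m
    row = [sum(obs[i][j] for j in range(n)) for i in range(n)]
    col = [sum(obs[i][j] for i in range(n)) for j in range(n)]
    num = den = 0.0
    for i in range(n):
        for j in range(n):
            w = (i - j) ** 2 / (n - 1) ** 2
            num += w * obs[i][j]
            den += w * row[i] * col[j]
    return 1.0 - num / den


def oracle_welch(xs, ys):
    nx, ny = len(xs), len(ys)
    mx, my = sum(xs) / nx, sum(ys) / ny
    vx = sum((x - mx) ** 2 for x in xs) / (nx - 1)
    vy = sum((y - my) ** 2 for y in ys) / (ny - 1)
    se2 = vx / nx + vy / ny
    t = (mx - my) / math.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    return t, df
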