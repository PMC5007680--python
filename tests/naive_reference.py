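"""Independent naive reference implementations used as test oracles.

Deliberately written with explicit Python loops, straight from the
definitions, sharing no code with the package under test.
"""


def naive_msr(matrix) -> float:
    """Four-loop mean squared residue: r_ij = b_ij - rowmean_i - colmean_j
    + overallmean; MSR = sum(r_ij^2) / (I*J)."""
    rows = [list(map(float, row)) for row in matrix]
    I = len(rows)
    J = len(rows[0])
    row_mean = [0.0] * I
    for i in range(I):
        s = 0.0
        for j in range(J):
            s += rows[i][j]
        row_mean[i] = s / J
    col_mean = [0.0] * J
    for j in range(J):
        s = 0.0
        for i in range(I):
            s += rows[i][j]
        col_mean[j] = s / I
    total = 0.0
    for i in range(I):
        for j in range(J):
            total += rows[i][j]
    overall = total / (I * J)
    acc = 0.0
    for i in range(I):
        for j in range(J):
            r = rows[i][j] - row_mean[i] - col_mean[j] + overall
            acc += r * r
    return acc / (I * J)


def naive_best(values, direction="maximize"):
    """Brute-force best value with earliest-index tie-breaking."""
    best = values[0]
    for v in values[1:]:
        if (direction == "maximize" and v > best) or \
           (direction == "minimize" and v < best):
            best = v
    return best


def naive_loocv_nearest_centroid(X, y):
    """Hand-rolled LOOCV with a nearest-centroid rule (sorted-class ties)."""
    n = len(X)
    correct = 0
    for i in range(n):
        train = [(X[j], y[j]) for j in range(n) if j != i]
        classes = sorted({lab for _, lab in train})
        best_class, best_d = None, None
        for c in classes:
            members = [x for x, lab in train if lab == c]
            centroid = [sum(col) / len(members) for col in zip(*members)]
            d = sum((a - b) ** 2 for a, b in zip(X[i], centroid))
            if best_d is None or d < best_d:
                best_class, best_d = c, d
        if best_class == y[i]:
            correct += 1
    return correct / n
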