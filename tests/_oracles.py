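"""Independent brute-force oracles, deliberately coded from first principles
and kept free of any balancesel implementation code."""


def smd_oracle(mean1, sd1, n1, mean2, sd2, n2, variant):
    """Standardized mean difference, written out step by step."""
    if variant == "paper":
        term_a = sd1 * sd1 / n1 + sd2 * sd2 / n2
        term_b = (n1 * n2) / (n1 + n2)
        denom = (term_a * term_b) ** 0.5
    elif variant == "cohen_pooled":
        num = (n1 - 1) * sd1 * sd1 + (n2 - 1) * sd2 * sd2
        denom = (num / (n1 + n2 - 2)) ** 0.5
    else:
        raise ValueError(variant)
    return (mean1 - mean2) / denom


def spearman_oracle_no_ties(x, y):
    """Classic 1 - 6*sum(d^2)/(n(n^2-1)) formula; valid without ties."""
    n = len(x)
    rank_x = [sorted(x).index(v) + 1 for v in x]
    rank_y = [sorted(y).index(v) + 1 for v in y]
    d2 = sum((rx - ry) ** 2 for rx, ry in zip(rank_x, rank_y))
    return 1.0 - 6.0 * d2 / (n * (n * n - 1))


def bh_oracle(pvals):
    """Benjamini-Hochberg step-up adjusted p-values."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        value = pvals[i] * m / rank_from_top
        running_min = min(running_min, value)
        adjusted[i] = min(running_min, 1.0)
    return adjusted


def icc21_anova_oracle(pairs):
    """ICC(2,1) via longhand two-way ANOVA mean squares (k = 2 raters)."""
    n = len(pairs)
    k = 2
    all_vals = [v for row in pairs for v in row]
    grand = sum(all_vals) / (n * k)
    row_means = [sum(row) / k for row in pairs]
    col_means = [sum(row[j] for row in pairs) / n for j in range(k)]
    ss_rows = k * sum((rm - grand) ** 2 for rm in row_means)
    ss_cols = n * sum((cm - grand) ** 2 for cm in col_means)
    ss_total = sum((v - grand) ** 2 for v in all_vals)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


def prune_all_orders(ids, abs_rho, abs_smd, st_dt_pairs, threshold):
    """Brute force over all removal orders respecting the two pruning rules.

    ``abs_rho``: dict[(a, b)] -> |rho| (keys sorted pairs); ``st_dt_pairs``:
    set of sorted (a, b) tuples that are ST/DT instantiations of one base,
    with the DT member listed second in a companion dict ``st_dt_pairs[(a,b)]
    = dt_member``.  Returns the set of reachable terminal survivor
    frozensets.
    """

    def violations(alive):
        out = []
        alive_sorted = sorted(alive)
        for i, a in enumerate(alive_sorted):
            for b in alive_sorted[i + 1 :]:
                if abs_rho.get((a, b), 0.0) > threshold:
                    out.append((a, b))
        return out

    def removal_of(pair):
        if pair in st_dt_pairs:
            return st_dt_pairs[pair]
        a, b = pair
        if abs_smd[a] < abs_smd[b] or (abs_smd[a] == abs_smd[b] and a > b):
            return a
        return b

    terminals = set()

    def recurse(alive):
        pairs = violations(alive)
        if not pairs:
            terminals.add(frozenset(alive))
            return
        for pair in pairs:
            recurse(alive - {removal_of(pair)})

    recurse(frozenset(ids))
    return terminals


def prune_min_removal(ids, abs_rho, abs_smd, st_dt_pairs, threshold):
    """Terminal survivor sets of maximal size among all reachable orders."""
    terminals = prune_all_orders(ids, abs_rho, abs_smd, st_dt_pairs, threshold)
    best = max(len(t) for t in terminals)
    return {t for t in terminals if len(t) == best}
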