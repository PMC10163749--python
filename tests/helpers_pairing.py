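"""Independent pick-the-best oracle shared by the pairing tests."""


def recursive_pick_the_best(matrix):
    """Repeatedly scan for the maximum remaining entry (no sorting).

    Mirrors the documented pick-the-best process one selection at a time,
    with ties broken by (row, column) scan order; used as an independent
    cross-check of the sort-based implementation.
    """
    n, m = len(matrix), len(matrix[0])
    used_i, used_j, pairs = set(), set(), []
    while True:
        best = None
        for i in range(n):
            if i in used_i:
                continue
            for j in range(m):
                if j in used_j or matrix[i][j] is None:
                    continue
                if best is None or matrix[i][j] > best[2]:
                    best = (i, j, matrix[i][j])
        if best is None:
            break
        used_i.add(best[0])
        used_j.add(best[1])
        pairs.append(best)
    pairs.sort()
    return pairs, sum(1 for _, _, llr in pairs if llr > 0)
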