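"""Exhaustive 2×2 table generator shared by the enumeration checks."""


def all_tables_up_to(n_max):
    """Yield every nonnegative 2×2 table (a, b, c, d) with 1 ≤ n ≤ n_max
    and no empty margin (those are degenerate by convention)."""
    for n in range(1, n_max + 1):
        for row1 in range(1, n):
            for col1 in range(1, n):
                lo = max(0, row1 + col1 - n)
                hi = min(row1, col1)
                for a in range(lo, hi + 1):
                    yield a, row1 - a, col1 - a, n - row1 - col1 + a
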