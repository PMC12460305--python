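"""Independent brute-force reference implementations used by the tests."""


def lz76_oracle(s: str) -> int:
    """Exhaustive-history Lempel-Ziv phrase count by literal substring search:
    each phrase is extended while it still occurs in everything preceding its
    final character."""
    n = len(s)
    idx, c = 0, 0
    while idx < n:
        l = 1
        while idx + l <= n and s[idx: idx + l] in s[0: idx + l - 1]:
            l += 1
        c += 1
        idx += l
    return c
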