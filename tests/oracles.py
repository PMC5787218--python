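"""Independent brute-force oracles the implementation is checked against.

These deliberately use the most literal algorithm available (full
Gotoh dynamic programming with explicit loops, sliding-window scans,
exhaustive enumeration) and share no code with the package's engines.
"""

NEG = -(10 ** 9)


def gotoh_best_score(query: str, subject: str, match=1, mismatch=-2,
                     gap_open=-5, gap_extend=-2) -> int:
    """Best local alignment score by full three-matrix DP (affine gaps:
    a gap of length L costs gap_open + L * gap_extend)."""
    m, n = len(query), len(subject)
    H = [[0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]
    F = [[NEG] * (n + 1) for _ in range(m + 1)]
    best = 0
    for i in range(1, m + 1):
        qi = query[i - 1]
        Hi, Hp = H[i], H[i - 1]
        Ei, Fp, Fi = E[i], F[i - 1], F[i]
        for j in range(1, n + 1):
            Ei[j] = max(Hi[j - 1] + gap_open + gap_extend,
                        Ei[j - 1] + gap_extend)
            Fi[j] = max(Hp[j] + gap_open + gap_extend, Fp[j] + gap_extend)
            sub = match if (qi == subject[j - 1] and qi != "N") else mismatch
            h = max(0, Hp[j - 1] + sub, Ei[j], Fi[j])
            Hi[j] = h
            if h > best:
                best = h
    return best


def scan_primer_sites(template: str, probe: str) -> list[int]:
    """All start positions of ``probe`` by a sliding-window scan."""
    probe = probe.upper()
    t = template.upper()
    return [i for i in range(len(t) - len(probe) + 1)
            if t[i:i + len(probe)] == probe]


def scan_tsd(flank5: str, flank3: str, lo=5, hi=15) -> str | None:
    """Exhaustive scan over all lengths for the longest suffix/prefix
    duplication within [lo, hi]."""
    best = None
    for length in range(lo, min(hi, len(flank5), len(flank3)) + 1):
        if flank5[-length:] == flank3[:length]:
            best = flank5[-length:]
    return best


def enumerate_amplicons(template: str, fwd: str, rev: str,
                        max_len: int) -> set[tuple[int, int]]:
    """All properly oriented primer-site spans by exhaustive enumeration."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

    def rc(s):
        return "".join(comp[b] for b in reversed(s.upper()))

    spans = set()
    for p1, p2 in ((fwd, rev), (rev, fwd)):
        starts = scan_primer_sites(template, p1)
        rev_starts = scan_primer_sites(template, rc(p2))
        for i in starts:
            for j in rev_starts:
                end = j + len(p2)
                if j >= i and end > i and end - i <= max_len:
                    spans.add((i, end))
    return spans
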