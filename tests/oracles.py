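"""Independent brute-force reference implementations used only by tests.

These deliberately share no code with the package: binding-site search is a
character-by-character sliding window, the dimer score enumerates alignments
with explicit string reversal, and the melting temperature is a hand-summed
nearest-neighbor calculation from the published unified duplex parameters.
"""

import math

IUPAC_SETS = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"}, "B": {"C", "G", "T"},
    "D": {"A", "G", "T"}, "H": {"A", "C", "T"}, "V": {"A", "C", "G"},
    "N": {"A", "C", "G", "T"},
}

COMPLEMENT = {
    "A": "T", "T": "A", "C": "G", "G": "C", "R": "Y", "Y": "R", "S": "S",
    "W": "W", "K": "M", "M": "K", "B": "V", "V": "B", "D": "H", "H": "D",
    "N": "N",
}


def revcomp(seq):
    return "".join(COMPLEMENT[c] for c in reversed(seq))


def naive_binding_sites(primer, template, max_mismatch, anchor_len):
    """All (strand, start, mismatches) tuples, brute force on both strands.

    A template 'N' never matches. Plus strand: primer as written along the
    template, 3' anchor at the window's right edge. Minus strand: reverse
    complement of the primer along the template, 3' anchor at the left edge.
    """
    m, n = len(primer), len(template)
    hits = []
    for strand, probe in (("plus", primer), ("minus", revcomp(primer))):
        for start in range(n - m + 1):
            window = template[start:start + m]
            mism = [
                not (t in IUPAC_SETS[p] and t != "N")
                for p, t in zip(probe, window)
            ]
            if sum(mism) > max_mismatch:
                continue
            anchor = mism[m - anchor_len:] if strand == "plus" else mism[:anchor_len]
            if anchor_len and any(anchor):
                continue
            hits.append((strand, start, sum(mism)))
    return sorted(hits, key=lambda h: (h[0] != "plus", h[1]))


def naive_dimer_score(a, b, window=5):
    """Exhaustive ungapped antiparallel alignment scan."""
    rb = b[::-1]  # b written 3'->5'
    best = best3 = 0
    for offset in range(-(len(rb) - 1), len(a)):
        total = total3 = 0
        for i in range(len(a)):
            j = i - offset
            if 0 <= j < len(rb):
                b_index = len(b) - 1 - j
                if COMPLEMENT.get(a[i]) == rb[j] and a[i] in "ACGT":
                    total += 1
                    if i >= len(a) - window or b_index >= len(b) - window:
                        total3 += 1
        best = max(best, total)
        best3 = max(best3, total3)
    return best, best3


# Unified nearest-neighbor duplex parameters (dH kcal/mol, dS cal/mol/K),
# expanded to all 16 dinucleotide stacks.
NN_PARAMS = {
    "AA": (-7.9, -22.2), "TT": (-7.9, -22.2),
    "AT": (-7.2, -20.4), "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2), "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}
INIT_GC = (0.1, -2.8)
INIT_AT = (2.3, 4.1)
R_GAS = 1.987  # cal / (mol K)


def naive_tm(seq, na_mM=50.0, primer_nM=400.0):
    """Hand-summed nearest-neighbor Tm with entropy salt correction.

    Tm = 1000 dH / (dS + R ln(Ct/4)) - 273.15, Ct the total strand
    concentration; dS is corrected by 0.368 (N-1) ln[Na+].
    """
    dh = ds = 0.0
    for end in (seq[0], seq[-1]):
        inc = INIT_GC if end in "GC" else INIT_AT
        dh += inc[0]
        ds += inc[1]
    for i in range(len(seq) - 1):
        pair = NN_PARAMS[seq[i:i + 2]]
        dh += pair[0]
        ds += pair[1]
    ds += 0.368 * (len(seq) - 1) * math.log(na_mM / 1000.0)
    ct = primer_nM * 1e-9
    return 1000.0 * dh / (ds + R_GAS * math.log(ct / 4.0)) - 273.15
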