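"""Independent brute-force oracles shared by the test modules.

These deliberately avoid the implementation's code paths: the binomial
oracle enumerates the pmf with exact combinatorics, and the SNV census
oracle mutates the full nucleotide sequence and re-translates the whole
protein with Biopython, comparing protein strings.
"""

import math

from Bio.Seq import Seq

from ihmburden._aa import PAPER_SCALE


def binom_oracle(k, n, p0, sided="two"):
    pmf = [math.comb(n, i) * p0 ** i * (1 - p0) ** (n - i) for i in range(n + 1)]
    if sided == "greater":
        return sum(pmf[k:])
    cutoff = pmf[k] * (1 + 1e-7)
    return min(1.0, sum(p for p in pmf if p <= cutoff))


def census_oracle(cds, scale=PAPER_SCALE):
    """(n_codons, syn, mis, non, neg, neu, pos) by full re-translation."""
    ref_prot = str(Seq(cds).translate())
    if ref_prot.endswith("*"):
        cds = cds[:-3]
        ref_prot = ref_prot[:-1]
    syn = mis = non = 0
    neg = neu = pos = 0
    for i in range(len(cds)):
        for b in "ACGT":
            if b == cds[i]:
                continue
            mut_prot = str(Seq(cds[:i] + b + cds[i + 1:]).translate())
            diffs = [j for j in range(len(ref_prot)) if mut_prot[j] != ref_prot[j]]
            if not diffs:
                syn += 1
            elif mut_prot[diffs[0]] == "*":
                non += 1
            else:
                mis += 1
                dq = scale.charge(mut_prot[diffs[0]]) - scale.charge(ref_prot[diffs[0]])
                neg += dq < 0
                neu += dq == 0
                pos += dq > 0
    return (len(cds) // 3, syn, mis, non, neg, neu, pos)
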