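"""Independent reference implementations used only to check maexp.

Each oracle takes a deliberately different route from the library code:
numerical CDF inversion instead of chi-square quantiles, per-start
string scanning instead of vectorized run detection, and whole-protein
Biopython translation instead of single-codon arithmetic.
"""

from scipy.optimize import brentq
from scipy.stats import poisson


def poisson_ci_numeric(count, level=0.95):
    """Exact Poisson CI by numerically inverting the Poisson CDF.

    The lower bound solves P(X >= count; lam) = alpha/2, the upper bound
    P(X <= count; lam) = alpha/2, for unit exposure.
    """
    alpha = 1.0 - level
    hi = 10.0 * count + 50.0
    if count == 0:
        low = 0.0
    else:
        low = brentq(lambda lam: poisson.sf(count - 1, lam) - alpha / 2, 1e-12, hi, xtol=1e-12)
    high = brentq(lambda lam: poisson.cdf(count, lam) - alpha / 2, 1e-12, hi, xtol=1e-12)
    return low, high


def _primitive(motif):
    k = len(motif)
    return not any(k % d == 0 and motif == motif[:d] * (k // d) for d in range(1, k))


def brute_force_ssrs(seq, thresholds):
    """Quadratic-style tandem-repeat scan: try every start, extend right."""
    seq = seq.upper()
    L = len(seq)
    candidates = []
    for k in range(1, 7):
        for i in range(L - k):
            if seq[i] != seq[i + k]:
                continue
            if i > 0 and seq[i - 1] == seq[i - 1 + k]:
                continue  # not left-maximal: same array starts earlier
            x = i
            while x + k < L and seq[x] == seq[x + k]:
                x += 1
            end = x + k
            if end - i < k * thresholds[k]:
                continue
            if not _primitive(seq[i : i + k]):
                continue
            candidates.append((i, end, seq[i : i + k]))
    # same resolution rule, independently coded with O(n^2) overlap checks
    candidates.sort(key=lambda c: (-(c[1] - c[0]), len(c[2]), c[0]))
    accepted = []
    for c in candidates:
        if all(c[1] <= a[0] or a[1] <= c[0] for a in accepted):
            accepted.append(c)
    accepted.sort()
    return accepted


def brute_force_ns_ratio(genome, titv, ti_weight_factor=2.0):
    """NS:S expectation by mutating every coding site and translating the
    whole protein with Biopython (bacterial table)."""
    from Bio.Seq import Seq

    w_ti = ti_weight_factor * titv
    purines = set("AG")
    ns_w = s_w = 0.0
    for cds in genome.cds:
        sub = genome.seq[cds.start : cds.end]
        cseq = str(Seq(sub).reverse_complement()) if cds.strand == "-" else sub
        prot = str(Seq(cseq).translate(table=11))
        for i in range(len(cseq)):
            for alt in "ACGT":
                if alt == cseq[i]:
                    continue
                w = w_ti if (cseq[i] in purines) == (alt in purines) else 1.0
                mutated = cseq[:i] + alt + cseq[i + 1 :]
                if str(Seq(mutated).translate(table=11)) == prot:
                    s_w += w
                else:
                    ns_w += w
    return ns_w / s_w
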