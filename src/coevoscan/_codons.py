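"""Shared codon bookkeeping for simulation and dN/dS counting.

Uses the standard genetic code from Biopython.  Site counting follows the
Nei-Gojobori convention in which each codon position contributes the fraction
of its three possible single-nucleotide changes that are synonymous;
mutations to stop codons count as nonsynonymous for site bookkeeping (so
synonymous + nonsynonymous sites always sum to 3 per codon) but paths through
stop codons are excluded when counting observed differences.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import permutations

from Bio.Data import CodonTable

NUCLEOTIDES = "ACGT"

_table = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(_table.stop_codons)
CODON_TO_AA = dict(_table.forward_table)
SENSE_CODONS = tuple(sorted(CODON_TO_AA))


def is_stop(codon: str) -> bool:
    return codon in STOP_CODONS


def neighbors(codon: str):
    """All 9 single-nucleotide mutants of a codon, with position and class.

    Yields ``(position, mutant, kind)`` with kind in {"syn", "nonsyn", "stop"}.
    """
    aa = CODON_TO_AA[codon]
    for pos in range(3):
        for nt in NUCLEOTIDES:
            if nt == codon[pos]:
                continue
            mut = codon[:pos] + nt + codon[pos + 1 :]
            if mut in STOP_CODONS:
                kind = "stop"
            elif CODON_TO_AA[mut] == aa:
                kind = "syn"
            else:
                kind = "nonsyn"
            yield pos, mut, kind


#: codon -> (synonymous sites, nonsynonymous sites); sums to 3.0
SITE_COUNTS = {}
#: codon -> tuple of (pos, mutant) for synonymous / nonsynonymous mutants
SYN_MUTANTS = {}
NONSYN_MUTANTS = {}
for _codon in SENSE_CODONS:
    _syn, _non = [], []
    for _pos, _mut, _kind in neighbors(_codon):
        if _kind == "syn":
            _syn.append((_pos, _mut))
        else:
            _non.append((_pos, _mut, _kind))
    SITE_COUNTS[_codon] = (len(_syn) / 3.0, 3.0 - len(_syn) / 3.0)
    SYN_MUTANTS[_codon] = tuple(_syn)
    NONSYN_MUTANTS[_codon] = tuple((p, m) for p, m, k in _non if k == "nonsyn")


@lru_cache(maxsize=None)
def pathway_differences(codon_a: str, codon_b: str):
    """Average synonymous/nonsynonymous difference counts between two codons.

    Considers all orderings of the differing positions (pathways), weights
    them equally, and skips pathways passing through a stop codon.  Returns
    ``(syn, nonsyn)``; their sum equals the nucleotide difference count
    whenever at least one stop-free pathway exists.
    """
    diff = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff:
        return 0.0, 0.0
    totals = []
    for order in permutations(diff):
        cur = codon_a
        syn = non = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                ok = False
                break
            if CODON_TO_AA[nxt] == CODON_TO_AA[cur]:
                syn += 1
            else:
                non += 1
            cur = nxt
        if ok:
            totals.append((syn, non))
    if not totals:
        # all pathways pass through stops; fall back to counting every
        # changed position as nonsynonymous
        return 0.0, float(len(diff))
    s = sum(t[0] for t in totals) / len(totals)
    n = sum(t[1] for t in totals) / len(totals)
    return s, n
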