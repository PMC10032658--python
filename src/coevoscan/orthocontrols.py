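"""Control-gene construction: orthologue scoring, filtering and dN/dS.

To judge whether a focal gene's rate--trait correlation is unusual, a cohort
of control genes with comparable statistical power is needed.  This module
implements that construction: BLOSUM62-scored semi-global alignment of a
human query protein against candidate orthologue sequences, reciprocal-best
acceptance, a sequential filter cascade on exon count / length / orthologue
completeness, a per-gene alignment information content that discounts gapped
columns by the tree branch length they lose, Nei-Gojobori (1986) dN/dS
counting, and the log(dS) outlier filter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

from coevoscan import _codons
from coevoscan.tree import Phylogeny

__all__ = [
    "score_candidate",
    "Hit",
    "OrthologueDecision",
    "reciprocal_best",
    "CandidateGene",
    "select_controls",
    "AlignmentStats",
    "alignment_info_content",
    "NG86Result",
    "ng86_dnds",
    "ds_outlier_filter",
]

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def _make_aligner() -> PairwiseAligner:
    # semi-global: end gaps free so coverage of the query has a clean meaning;
    # a gap of length L costs 3 + L (opening 3, extension 1 per base)
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = _BLOSUM62
    aligner.open_internal_gap_score = -4.0
    aligner.extend_internal_gap_score = -1.0
    aligner.end_insertion_score = 0.0
    aligner.end_deletion_score = 0.0
    return aligner


def _forward_frames(dna: str):
    """Translations of the three forward frames without internal stops.

    A trailing stop is trimmed; frames with an internal stop (or a trailing
    partial codon producing nothing) are dropped.
    """
    dna = dna.upper().replace("U", "T")
    out = []
    for frame in range(3):
        sub = dna[frame:]
        sub = sub[: len(sub) - len(sub) % 3]
        if not sub:
            continue
        aa = str(Seq(sub).translate())
        if aa.endswith("*"):
            aa = aa[:-1]
        if not aa or "*" in aa:
            continue
        out.append(aa)
    return out


def score_candidate(query_protein: str, target_sequence: str, min_coverage: float = 0.30):
    """Score a candidate orthologue DNA sequence against a human protein.

    The best of the three forward reading frames is aligned to the query
    protein (BLOSUM62, gap opening 3, extension 1, free end gaps).  Coverage
    is the fraction of query residues aligned to a target residue; the
    candidate is eligible iff coverage >= ``min_coverage``.

    Returns ``(score, coverage, eligible)``; an empty or untranslatable
    target yields ``(-inf, 0.0, False)``.
    """
    query_protein = query_protein.upper().rstrip("*")
    if not query_protein:
        raise ValueError("empty query protein")
    frames = _forward_frames(target_sequence)
    if not frames:
        return float("-inf"), 0.0, False
    aligner = _make_aligner()
    best_score, best_cov = float("-inf"), 0.0
    for aa in frames:
        aln = aligner.align(query_protein, aa)[0]
        score = float(aln.score)
        if score > best_score:
            aligned_query = sum(int(e - s) for s, e in aln.aligned[0])
            best_score = score
            best_cov = aligned_query / len(query_protein)
    return best_score, best_cov, best_cov >= min_coverage


@dataclass
class Hit:
    """One alignment hit: score, matched sequence, and (for back hits)
    the 0-based half-open interval it occupies on the human CDS."""

    sequence: str
    score: float
    cds_interval: tuple | None = None


@dataclass
class OrthologueDecision:
    accepted: bool
    reason: str
    sequence: str | None = None


def reciprocal_best(
    forward_hits,
    back_hit: Hit | None,
    cds_length: int,
    min_overlap: float = 0.10,
) -> OrthologueDecision:
    """Reciprocal-best acceptance of a candidate orthologue.

    The best-scoring forward hit is taken; if several hits tie at the maximum
    score they are accepted only when their sequences are identical.  The
    orthologue is then kept iff the back-aligned best hit overlaps at least
    ``min_overlap`` of the original human CDS positions.
    """
    forward_hits = list(forward_hits)
    if not forward_hits:
        return OrthologueDecision(False, "no forward hit")
    best = max(h.score for h in forward_hits)
    top = [h for h in forward_hits if h.score == best]
    if len({h.sequence for h in top}) > 1:
        return OrthologueDecision(False, "ambiguous tie: non-identical best hits")
    if back_hit is None or back_hit.cds_interval is None:
        return OrthologueDecision(False, "no back hit to the human CDS")
    s, e = back_hit.cds_interval
    overlap = max(0, min(e, cds_length) - max(s, 0))
    if overlap < min_overlap * cds_length:
        return OrthologueDecision(
            False,
            f"back hit overlaps {overlap / cds_length:.1%} of the CDS "
            f"(< {min_overlap:.0%})",
        )
    return OrthologueDecision(True, "reciprocal best", top[0].sequence)


# ---------------------------------------------------------------------------
# selection cascade
# ---------------------------------------------------------------------------


@dataclass
class CandidateGene:
    gene_id: str
    human_cds_length: int  # nucleotides
    n_coding_exons: int
    orthologue_lengths: dict = field(default_factory=dict)  # species -> nt length


def select_controls(
    candidates,
    required_species,
    cds_length_range: tuple = (291, 999),
    length_ratio_range: tuple = (0.5, 2.0),
):
    """Sequential control-gene filter cascade with per-stage tallies.

    Stages: (1) single coding exon; (2) human CDS length within
    ``cds_length_range`` (closed interval, nucleotides); (3) an orthologue
    present in every required species; (4) every orthologue length within
    [50%, 200%) of the human length (half-open on the upper bound).

    Returns ``(survivors, tallies)`` where tallies maps stage name -> number
    of genes remaining after that stage.
    """
    required_species = list(required_species)
    lo, hi = cds_length_range
    rlo, rhi = length_ratio_range
    tallies = {"input": len(list(candidates))}
    stage = [c for c in candidates if c.n_coding_exons == 1]
    tallies["single_exon"] = len(stage)
    stage = [c for c in stage if lo <= c.human_cds_length <= hi]
    tallies["cds_length"] = len(stage)
    stage = [
        c
        for c in stage
        if all(c.orthologue_lengths.get(s) is not None for s in required_species)
    ]
    tallies["orthologue_in_all_species"] = len(stage)
    survivors = []
    for c in stage:
        ok = True
        for s in required_species:
            ratio = c.orthologue_lengths[s] / c.human_cds_length
            if not (rlo <= ratio < rhi):
                ok = False
                break
        if ok:
            survivors.append(c)
    tallies["length_ratio"] = len(survivors)
    return survivors, tallies


# ---------------------------------------------------------------------------
# alignment information content
# ---------------------------------------------------------------------------


@dataclass
class AlignmentStats:
    gene_id: str
    lambda_total: float
    lambda_per_position: np.ndarray
    info_content: float  # mean(lambda_i / lambda_t), in [0, 1]


def alignment_info_content(
    alignment: dict, tree: Phylogeny, gene_id: str = ""
) -> AlignmentStats:
    """Average branch-length retention of an alignment's columns.

    For column i, lambda_i is the total branch length of the subtree induced
    by the species with a non-gap character (dangling branches fully pruned);
    columns with fewer than two non-gap species contribute lambda_i = 0.  The
    information content is mean(lambda_i / lambda_t) with lambda_t the full
    tree's total branch length: 1 for a gapless alignment, smaller as gaps
    remove lineages.
    """
    species = list(alignment)
    missing = set(species) - set(tree.leaf_labels)
    if missing:
        raise KeyError(f"alignment species not in tree: {sorted(missing)}")
    lengths = {len(s) for s in alignment.values()}
    if len(lengths) != 1:
        raise ValueError("alignment rows must have equal length")
    p = lengths.pop()
    lam_t = tree.total_branch_length()
    cache: dict = {}
    lam = np.zeros(p)
    for i in range(p):
        present = frozenset(s for s in species if alignment[s][i] not in "-.")
        if len(present) < 2:
            continue
        if present not in cache:
            cache[present] = tree.prune_to(present).total_branch_length()
        lam[i] = cache[present]
    return AlignmentStats(
        gene_id=gene_id,
        lambda_total=lam_t,
        lambda_per_position=lam,
        info_content=float(np.mean(lam / lam_t)) if p else 0.0,
    )


# ---------------------------------------------------------------------------
# NG86 dN/dS
# ---------------------------------------------------------------------------


@dataclass
class NG86Result:
    dn: float
    ds: float
    omega: float  # NaN when dS == 0
    omega_defined: bool
    syn_sites: float
    nonsyn_sites: float
    syn_diffs: float
    nonsyn_diffs: float


def _jukes_cantor(p: float) -> float:
    if p <= 0:
        return 0.0
    if p >= 0.75:
        return math.inf
    return -0.75 * math.log(1 - 4.0 * p / 3.0)


def ng86_dnds(codon_seq_a: str, codon_seq_b: str) -> NG86Result:
    """Nei-Gojobori (1986) pairwise dN/dS with Jukes-Cantor correction.

    Synonymous/nonsynonymous site counts are averaged over the two
    sequences; differences are counted by equal-weight pathway averaging
    (stop-codon pathways excluded).  dN and dS are symmetric in argument
    order, and syn + nonsyn sites always total 3 x the codon count.
    """
    a, b = codon_seq_a.upper(), codon_seq_b.upper()
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    if len(a) % 3:
        raise ValueError("sequence length must be divisible by 3")
    if "-" in a or "-" in b:
        raise ValueError("sequences must be gap-free")
    n_codons = len(a) // 3
    syn_sites = nonsyn_sites = 0.0
    syn_d = nonsyn_d = 0.0
    for k in range(n_codons):
        ca, cb = a[3 * k : 3 * k + 3], b[3 * k : 3 * k + 3]
        for c in (ca, cb):
            if _codons.is_stop(c):
                raise ValueError(f"stop codon {c} at codon position {k}")
        sa, na = _codons.SITE_COUNTS[ca]
        sb, nb = _codons.SITE_COUNTS[cb]
        syn_sites += 0.5 * (sa + sb)
        nonsyn_sites += 0.5 * (na + nb)
        sd, nd = _codons.pathway_differences(ca, cb)
        syn_d += sd
        nonsyn_d += nd
    ps = syn_d / syn_sites if syn_sites > 0 else 0.0
    pn = nonsyn_d / nonsyn_sites if nonsyn_sites > 0 else 0.0
    ds = _jukes_cantor(ps)
    dn = _jukes_cantor(pn)
    defined = ds > 0 and math.isfinite(ds)
    return NG86Result(
        dn=dn,
        ds=ds,
        omega=dn / ds if defined else float("nan"),
        omega_defined=defined,
        syn_sites=syn_sites,
        nonsyn_sites=nonsyn_sites,
        syn_diffs=syn_d,
        nonsyn_diffs=nonsyn_d,
    )


# ---------------------------------------------------------------------------
# dS outlier filter
# ---------------------------------------------------------------------------


def ds_outlier_filter(ds_treelengths: dict, n_sd: float = 3.0):
    """Drop genes whose log(dS) tree length lies >= ``n_sd`` SD from the mean.

    Single pass: mean and SD are computed once over the full input set,
    prospective outliers included; the filter is not iterated.  Returns
    ``(retained gene ids, removed gene ids)``.
    """
    for g, v in ds_treelengths.items():
        if v <= 0:
            raise ValueError(f"dS tree length for {g} must be > 0")
    genes = list(ds_treelengths)
    logs = np.log([ds_treelengths[g] for g in genes])
    sd = logs.std(ddof=0)
    if sd == 0:
        return genes, []
    z = np.abs(logs - logs.mean()) / sd
    retained = [g for g, zi in zip(genes, z) if zi < n_sd]
    removed = [g for g, zi in zip(genes, z) if zi >= n_sd]
    return retained, removed
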