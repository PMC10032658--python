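"""Synthetic-data generators for the full co-evolution pipeline.

Everything the downstream analyses consume can be simulated here with the
statistical structure those analyses assume:

* pure-birth ultrametric phylogenies;
* multivariate-Brownian co-evolution of a log substitution rate (log omega)
  with log brain size, log gyrification index and log body mass;
* codon alignments whose branch-wise nonsynonymous/synonymous substitution
  ratio follows the simulated per-branch omega;
* tiled reporter libraries (94-mers stepped by 40 bases by default) with
  uniqueness- and composition-constrained barcodes;
* negative-binomial barcode counts for plasmid and RNA replicates, with
  optional FASTQ fixture emission;
* binomial proliferation counts with batch effects.

Every generator is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from coevoscan import _codons
from coevoscan.tree import Phylogeny

__all__ = [
    "EvolScenario",
    "Tile",
    "TileDesign",
    "CountMatrix",
    "TraitSimulation",
    "CONSTANT_REGION",
    "KPNI_SITE",
    "XBAI_SITE",
    "simulate_tree",
    "simulate_traits_and_rates",
    "simulate_rate_on_traits",
    "simulate_codon_alignment",
    "barcode_ok",
    "generate_barcodes",
    "tile_cre",
    "design_library",
    "simulate_mpra_counts",
    "write_fastq",
    "simulate_proliferation",
]

#: first 20 bases of the reporter ORF, shared by every read after the barcode
CONSTANT_REGION = "TCTAGAGTCGCGGCCTTACT"
KPNI_SITE = "GGTACC"
XBAI_SITE = "TCTAGA"

TRAIT_COLUMNS = ["log_omega", "log_brain", "log_gi", "log_body"]


# ---------------------------------------------------------------------------
# phylogeny + trait simulation
# ---------------------------------------------------------------------------


def simulate_tree(n_species: int, seed: int, birth_rate: float = 1.0) -> Phylogeny:
    """Ultrametric pure-birth (Yule) tree with ``n_species`` leaves.

    Waiting times between speciation events are exponential with rate
    ``birth_rate * k`` for k extant lineages; every tip ends at the present,
    so all root-to-tip path lengths are equal.
    """
    if n_species < 2:
        raise ValueError("n_species must be >= 2")
    rng = np.random.default_rng(seed)
    # grow the tree: each lineage records (parent_slot, birth_time)
    parent_of = {0: (-1, 0.0), 1: (0, 0.0), 2: (0, 0.0)}  # root splits at t=0
    active = [1, 2]
    next_id = 3
    t = 0.0
    split_time = {0: 0.0}
    while len(active) < n_species:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        idx = rng.integers(len(active))
        node = active.pop(idx)
        split_time[node] = t
        for _ in range(2):
            parent_of[next_id] = (node, t)
            active.append(next_id)
            next_id += 1
    t_end = t + rng.exponential(1.0 / (birth_rate * len(active)))
    # convert to arrays in preorder
    children_of = {}
    for nid, (p, _) in parent_of.items():
        children_of.setdefault(p, []).append(nid)
    order = []
    stack = [0]
    while stack:
        nd = stack.pop()
        order.append(nd)
        stack.extend(reversed(children_of.get(nd, [])))
    index = {nid: i for i, nid in enumerate(order)}
    parent = np.array([index.get(parent_of[nid][0], -1) for nid in order])
    lengths = np.zeros(len(order))
    labels: list = [None] * len(order)
    leaf_counter = 0
    for nid in order:
        p, birth = parent_of[nid]
        end = split_time.get(nid, t_end)
        if p >= 0:
            lengths[index[nid]] = end - birth
        if nid not in children_of:
            labels[index[nid]] = f"sp{leaf_counter:03d}"
            leaf_counter += 1
    return Phylogeny(parent=parent, lengths=lengths, labels=labels)


@dataclass
class EvolScenario:
    """Joint diffusion of (log omega, log brain, log GI, log body mass).

    ``sigma`` is the 4x4 symmetric positive-semidefinite diffusion (rate)
    matrix of the multivariate Brownian motion; ``root_state`` the state at
    the root on log scale.
    """

    sigma: np.ndarray
    root_state: np.ndarray
    seed: int = 0

    def __post_init__(self):
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.root_state = np.asarray(self.root_state, dtype=float)
        if self.sigma.shape != (4, 4) or self.root_state.shape != (4,):
            raise ValueError("sigma must be 4x4 and root_state length 4")
        if not np.allclose(self.sigma, self.sigma.T, atol=1e-10):
            raise ValueError("sigma must be symmetric")
        if np.linalg.eigvalsh(self.sigma).min() < -1e-10:
            raise ValueError("sigma must be positive semi-definite")

    @classmethod
    def from_correlations(
        cls,
        variances,
        corr_omega_brain: float = 0.0,
        corr_omega_gi: float = 0.0,
        corr_omega_body: float = 0.0,
        corr_brain_gi: float = 0.0,
        corr_brain_body: float = 0.0,
        corr_gi_body: float = 0.0,
        root_state=(0.0, 0.0, 0.0, 0.0),
        seed: int = 0,
    ) -> "EvolScenario":
        v = np.asarray(variances, dtype=float)
        R = np.array(
            [
                [1.0, corr_omega_brain, corr_omega_gi, corr_omega_body],
                [corr_omega_brain, 1.0, corr_brain_gi, corr_brain_body],
                [corr_omega_gi, corr_brain_gi, 1.0, corr_gi_body],
                [corr_omega_body, corr_brain_body, corr_gi_body, 1.0],
            ]
        )
        s = np.sqrt(v)
        return cls(sigma=R * np.outer(s, s), root_state=np.asarray(root_state), seed=seed)


@dataclass
class TraitSimulation:
    """Output of :func:`simulate_traits_and_rates`."""

    traits: pd.DataFrame  # leaves x TRAIT_COLUMNS, log scale
    branch_omega: dict  # child node index -> omega on the branch above it
    node_states: np.ndarray  # n_nodes x 4


def simulate_traits_and_rates(tree: Phylogeny, scenario: EvolScenario) -> TraitSimulation:
    """Run the 4-dimensional Brownian motion along the tree.

    Node states evolve as ``x_child = x_parent + sqrt(t) * A z`` with
    ``A A' = sigma``; the omega attached to a branch is the exponential of
    the mean of its endpoint log-omega states, matching the branch-averaging
    of a Brownian rate process.
    """
    w, V = np.linalg.eigh(scenario.sigma)
    A = V @ np.diag(np.sqrt(np.maximum(w, 0.0)))
    rng = np.random.default_rng(scenario.seed)
    states = np.zeros((tree.n_nodes, 4))
    states[0] = scenario.root_state
    for i in range(1, tree.n_nodes):  # preorder: parent already set
        z = rng.standard_normal(4)
        states[i] = states[tree.parent[i]] + np.sqrt(tree.lengths[i]) * (A @ z)
    branch_omega = {
        i: float(np.exp(0.5 * (states[i, 0] + states[tree.parent[i], 0])))
        for i in range(1, tree.n_nodes)
    }
    leaves = tree.leaf_indices()
    traits = pd.DataFrame(
        states[leaves], index=[tree.labels[i] for i in leaves], columns=TRAIT_COLUMNS
    )
    traits.index.name = "species"
    return TraitSimulation(traits=traits, branch_omega=branch_omega, node_states=states)


def simulate_rate_on_traits(
    tree: Phylogeny,
    trait_states: np.ndarray,
    trait_dim: int,
    trait_var: float,
    rho: float,
    omega_var: float = 0.04,
    root_log_omega: float = 0.0,
    seed: int = 0,
):
    """Simulate one gene's log-omega Brownian motion conditionally on a given
    trait realisation.

    Per branch, the log-omega increment is ``rho`` times the standardized
    trait increment plus independent noise, so the increment correlation with
    the chosen trait equals ``rho`` while the trait path itself is shared
    across genes (as in a study where many genes face one phenotypic
    history).  Returns ``(leaf log-omega Series, branch_omega dict)``.
    """
    if not -1.0 <= rho <= 1.0:
        raise ValueError("rho must be in [-1, 1]")
    rng = np.random.default_rng(seed)
    logw = np.zeros(tree.n_nodes)
    logw[0] = root_log_omega
    s_w = np.sqrt(omega_var)
    for i in range(1, tree.n_nodes):
        t = tree.lengths[i]
        p = tree.parent[i]
        if t <= 0:
            logw[i] = logw[p]
            continue
        z_trait = (trait_states[i, trait_dim] - trait_states[p, trait_dim]) / np.sqrt(
            trait_var * t
        )
        z = rho * z_trait + np.sqrt(max(1 - rho**2, 0.0)) * rng.standard_normal()
        logw[i] = logw[p] + s_w * np.sqrt(t) * z
    branch_omega = {
        i: float(np.exp(0.5 * (logw[i] + logw[tree.parent[i]])))
        for i in range(1, tree.n_nodes)
    }
    leaves = tree.leaf_indices()
    series = pd.Series(
        logw[leaves], index=[tree.labels[i] for i in leaves], name="log_omega"
    )
    return series, branch_omega


# ---------------------------------------------------------------------------
# codon alignments
# ---------------------------------------------------------------------------


def simulate_codon_alignment(
    tree: Phylogeny,
    branch_omega: dict,
    n_codons: int,
    seed: int,
    mutation_rate: float = 1.0,
) -> dict:
    """Gapless codon alignment whose branch-wise dN/dS follows ``branch_omega``.

    Mutation proposals (uniform over the 9 single-nucleotide neighbours of a
    codon) arrive as a Poisson process along each branch; a proposal creating
    a stop codon is always rejected, a synonymous proposal is accepted with
    probability min(1, 1/omega) and a nonsynonymous one with probability
    min(1, omega) -- so accepted nonsynonymous and synonymous changes occur
    in the ratio omega while each acceptance probability stays <= 1.
    ``mutation_rate`` scales expected proposals per codon per unit
    branch length.  Returns species -> sequence.
    """
    if n_codons < 50:
        raise ValueError("n_codons must be >= 50")
    for pc in tree.edges():
        if pc[1] not in branch_omega:
            raise ValueError(f"branch_omega missing entry for child node {pc[1]}")
        if branch_omega[pc[1]] < 0:
            raise ValueError("omega must be non-negative")
    rng = np.random.default_rng(seed)
    sense = _codons.SENSE_CODONS
    root_seq = [sense[i] for i in rng.integers(len(sense), size=n_codons)]
    seqs: dict = {0: root_seq}
    for i in range(1, tree.n_nodes):
        parent_seq = seqs[tree.parent[i]]
        seq = list(parent_seq)
        omega = branch_omega[i]
        a_syn = min(1.0, 1.0 / omega) if omega > 0 else 1.0
        a_non = min(1.0, omega)
        n_events = rng.poisson(mutation_rate * tree.lengths[i] * n_codons)
        for _ in range(n_events):
            site = rng.integers(n_codons)
            codon = seq[site]
            pos = rng.integers(3)
            nt = _codons.NUCLEOTIDES[rng.integers(4)]
            if nt == codon[pos]:
                continue
            mut = codon[:pos] + nt + codon[pos + 1 :]
            if _codons.is_stop(mut):
                continue
            if _codons.CODON_TO_AA[mut] == _codons.CODON_TO_AA[codon]:
                accept = a_syn
            else:
                accept = a_non
            if rng.random() < accept:
                seq[site] = mut
        seqs[i] = seq
    return {
        tree.labels[i]: "".join(seqs[i]) for i in tree.leaf_indices()
    }


# ---------------------------------------------------------------------------
# tiling + barcodes
# ---------------------------------------------------------------------------


def barcode_ok(barcode: str, forbidden_seeds=()) -> bool:
    """Validate the barcode composition constraints.

    A barcode must contain all four nucleotides at least once, no run of four
    or more identical nucleotides, no KpnI (GGTACC) or XbaI (TCTAGA) site on
    the forward strand, and no substring from ``forbidden_seeds`` (e.g. a
    miRNA seed list, supplied by the caller since seed collections are
    database-version dependent).
    """
    if set("ACGT") - set(barcode):
        return False
    for nt in "ACGT":
        if nt * 4 in barcode:
            return False
    if KPNI_SITE in barcode or XBAI_SITE in barcode:
        return False
    for seed_seq in forbidden_seeds:
        if seed_seq and seed_seq in barcode:
            return False
    return True


def generate_barcodes(
    n: int, length: int, forbidden_seeds=(), seed: int = 0, max_attempts_per_barcode: int = 10_000
) -> list:
    """Draw ``n`` unique constraint-satisfying barcodes of ``length`` bases."""
    if length < 8:
        raise ValueError("barcode length must be >= 8")
    rng = np.random.default_rng(seed)
    out: list = []
    seen = set()
    attempts_left = max_attempts_per_barcode * n
    while len(out) < n:
        if attempts_left <= 0:
            raise RuntimeError(
                f"could not generate {n} barcodes of length {length} under the "
                f"constraints after {max_attempts_per_barcode * n} attempts"
            )
        attempts_left -= 1
        bc = "".join("ACGT"[i] for i in rng.integers(4, size=length))
        if bc in seen or not barcode_ok(bc, forbidden_seeds):
            continue
        seen.add(bc)
        out.append(bc)
    return out


def tile_cre(cre_length: int, tile_size: int = 94, step: int = 40) -> list:
    """Sliding-window decomposition of a regulatory element into tiles.

    Offsets advance by ``step``; if the last regular tile does not reach the
    element's end, a final tile is anchored flush at ``cre_length -
    tile_size`` so every base is covered.  Elements shorter than a tile yield
    a single full-length tile.  Returns [(offset, length), ...], 0-based
    half-open.
    """
    if cre_length < 1:
        raise ValueError("cre_length must be >= 1")
    if cre_length <= tile_size:
        return [(0, cre_length)]
    tiles = []
    offset = 0
    while offset + tile_size <= cre_length:
        tiles.append((offset, tile_size))
        offset += step
    last_end = tiles[-1][0] + tile_size
    if last_end < cre_length:
        tiles.append((cre_length - tile_size, tile_size))
    return tiles


@dataclass
class Tile:
    tile_id: str
    offset: int
    length: int
    barcode: str


@dataclass
class TileDesign:
    """Tiled decomposition of one regulatory element."""

    cre_id: str
    species: str
    cre_length: int
    tiles: list  # of Tile

    def __post_init__(self):
        offsets = [t.offset for t in self.tiles]
        if offsets != sorted(set(offsets)):
            raise ValueError("tile offsets must be strictly increasing")
        covered = set()
        for t in self.tiles:
            covered.update(range(t.offset, t.offset + t.length))
        if covered != set(range(self.cre_length)):
            raise ValueError("tiles must cover the element exactly")

    def barcode_map(self) -> dict:
        return {t.barcode: t.tile_id for t in self.tiles}


def design_library(
    cre_lengths: dict,
    tile_size: int = 94,
    step: int = 40,
    barcode_length: int = 10,
    forbidden_seeds=(),
    seed: int = 0,
    species: dict | None = None,
) -> list:
    """Build :class:`TileDesign` objects for a set of elements with
    library-wide unique barcodes."""
    layouts = {cid: tile_cre(ln, tile_size, step) for cid, ln in cre_lengths.items()}
    n_tiles = sum(len(v) for v in layouts.values())
    barcodes = generate_barcodes(n_tiles, barcode_length, forbidden_seeds, seed)
    designs = []
    k = 0
    for cid, layout in layouts.items():
        tiles = []
        for j, (off, ln) in enumerate(layout):
            tiles.append(Tile(f"{cid}_t{j}", off, ln, barcodes[k]))
            k += 1
        designs.append(
            TileDesign(
                cre_id=cid,
                species=(species or {}).get(cid, ""),
                cre_length=cre_lengths[cid],
                tiles=tiles,
            )
        )
    return designs


# ---------------------------------------------------------------------------
# MPRA counts
# ---------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """Tile x sample count table plus per-sample metadata.

    ``sample_meta`` is indexed by sample name with columns ``material``
    ("plasmid" or "rna"), ``cell_line`` and ``replicate``.
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self):
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        if list(self.counts.columns) != list(self.sample_meta.index):
            raise ValueError("sample_meta index must match count columns")
        for col in ("material", "cell_line", "replicate"):
            if col not in self.sample_meta.columns:
                raise ValueError(f"sample_meta missing column {col!r}")

    def plasmid_samples(self) -> list:
        return list(self.sample_meta.index[self.sample_meta["material"] == "plasmid"])

    def rna_samples(self, cell_line=None) -> list:
        m = self.sample_meta["material"] == "rna"
        if cell_line is not None:
            m &= self.sample_meta["cell_line"] == cell_line
        return list(self.sample_meta.index[m])


def _nb_counts(rng, mean, dispersion):
    mean = np.maximum(mean, 0.0)
    if dispersion <= 1e-12:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


def simulate_mpra_counts(
    designs,
    true_region_activity: dict,
    n_plasmid_reps: int = 3,
    cell_lines: dict | None = None,
    depth: int = 1_000_000,
    dispersion: float = 0.05,
    dropout: float = 0.0,
    seed: int = 0,
):
    """Negative-binomial barcode counts for plasmid and RNA replicates.

    Plasmid counts are NB around skewed library proportions; RNA counts are
    NB around plasmid proportion x the tile's activity (every tile inherits
    its element's ``true_region_activity``), renormalized to the sequencing
    ``depth``.  ``dropout`` zeroes each tile independently per RNA replicate.
    Returns ``(CountMatrix, manifest)`` where the manifest records the true
    per-tile activities and library proportions for recovery tests.
    """
    if cell_lines is None:
        cell_lines = {"lineA": 3}
    if not 0.0 <= dropout < 1.0:
        raise ValueError("dropout must be in [0, 1)")
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    for cid, act in true_region_activity.items():
        if act <= 0:
            raise ValueError(f"activity for {cid} must be > 0")
    rng = np.random.default_rng(seed)
    tile_ids, tile_act, tile_cre_id = [], [], []
    for d in designs:
        for t in d.tiles:
            tile_ids.append(t.tile_id)
            tile_act.append(true_region_activity[d.cre_id])
            tile_cre_id.append(d.cre_id)
    tile_act = np.asarray(tile_act)
    n_tiles = len(tile_ids)
    lib_w = rng.gamma(4.0, 1.0, size=n_tiles)
    lib_p = lib_w / lib_w.sum()
    cols, meta_rows = {}, []
    for r in range(1, n_plasmid_reps + 1):
        name = f"plasmid_rep{r}"
        cols[name] = _nb_counts(rng, depth * lib_p, dispersion)
        meta_rows.append((name, "plasmid", "", r))
    rna_w = lib_p * tile_act
    rna_p = rna_w / rna_w.sum()
    for line, n_reps in cell_lines.items():
        for r in range(1, n_reps + 1):
            name = f"{line}_rep{r}"
            mean = depth * rna_p
            c = _nb_counts(rng, mean, dispersion)
            if dropout > 0:
                c = np.where(rng.random(n_tiles) < dropout, 0, c)
            cols[name] = c
            meta_rows.append((name, "rna", line, r))
    counts = pd.DataFrame(cols, index=pd.Index(tile_ids, name="tile_id"))
    meta = pd.DataFrame(
        meta_rows, columns=["sample", "material", "cell_line", "replicate"]
    ).set_index("sample")
    manifest = pd.DataFrame(
        {
            "tile_id": tile_ids,
            "cre_id": tile_cre_id,
            "true_activity": tile_act,
            "library_proportion": lib_p,
        }
    ).set_index("tile_id")
    return CountMatrix(counts=counts, sample_meta=meta), manifest


def write_fastq(
    path,
    design_or_designs,
    tile_counts: dict,
    seed: int = 0,
    base_quality: int = 40,
    n_lowqual: int = 0,
    n_mismatch: int = 0,
):
    """Emit fixture reads (barcode + constant region, Phred+33) for one sample.

    ``tile_counts`` maps tile_id -> number of clean reads.  ``n_lowqual``
    extra reads carry one barcode base at Phred 9 and ``n_mismatch`` extra
    reads carry one substitution inside the constant region; both must be
    rejected by the read filter.
    """
    designs = (
        design_or_designs if isinstance(design_or_designs, (list, tuple)) else [design_or_designs]
    )
    tiles = {t.tile_id: t for d in designs for t in d.tiles}
    rng = np.random.default_rng(seed)
    qchar = chr(33 + base_quality)
    records = []
    for tid, n in tile_counts.items():
        bc = tiles[tid].barcode
        seq = bc + CONSTANT_REGION
        for i in range(n):
            records.append((f"{tid}_clean_{i}", seq, qchar * len(seq)))
    all_tiles = list(tiles.values())
    for i in range(n_lowqual):
        t = all_tiles[rng.integers(len(all_tiles))]
        seq = t.barcode + CONSTANT_REGION
        pos = rng.integers(len(t.barcode))
        qual = list(qchar * len(seq))
        qual[pos] = chr(33 + 9)
        records.append((f"lowq_{i}", seq, "".join(qual)))
    for i in range(n_mismatch):
        t = all_tiles[rng.integers(len(all_tiles))]
        pos = len(t.barcode) + rng.integers(len(CONSTANT_REGION))
        seq = list(t.barcode + CONSTANT_REGION)
        seq[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[pos]]
        records.append((f"mm_{i}", "".join(seq), qchar * (len(t.barcode) + len(CONSTANT_REGION))))
    with open(path, "w") as fh:
        for name, seq, qual in records:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")
    return len(records)


# ---------------------------------------------------------------------------
# proliferation
# ---------------------------------------------------------------------------


def simulate_proliferation(
    conditions,
    true_rates: dict,
    batch_effects: dict | None = None,
    cells_per_replicate: int = 200,
    n_replicates: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Binomial proliferation counts with additive batch effects on log-odds.

    Each replicate of a condition is assigned round-robin to the batches in
    ``batch_effects`` (log-odds shifts); successes are Binomial(gfp_total,
    expit(logit(rate) + shift)).  Columns: condition, batch, gfp_total,
    ki67_gfp.
    """
    from scipy.special import expit, logit

    if batch_effects is None:
        batch_effects = {"b1": 0.0}
    batches = list(batch_effects)
    rng = np.random.default_rng(seed)
    rows = []
    for cond in conditions:
        rate = true_rates[cond]
        if not 0.0 < rate < 1.0:
            raise ValueError(f"true rate for {cond} must be in (0, 1)")
        for r in range(n_replicates):
            batch = batches[r % len(batches)]
            p = float(expit(logit(rate) + batch_effects[batch]))
            total = cells_per_replicate
            rows.append(
                {
                    "condition": cond,
                    "batch": batch,
                    "gfp_total": total,
                    "ki67_gfp": int(rng.binomial(total, p)),
                }
            )
    return pd.DataFrame(rows)
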