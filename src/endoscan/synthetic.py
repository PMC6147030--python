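"""Seeded generators for synthetic inputs with the structure the screens assume.

The genome generator writes a bacterial-style chromosome: protein-coding
genes drawn base-by-base with codon-position-specific GC probabilities,
placed on alternating strands with random intergenic spacers.  A configured
subset of genes is "alien": their GC1/GC3 targets are shifted the same way
(so the deviations share a sign, the pattern the composition screen keys
on), and the hit generator gives them foreign-taxon similarity profiles.
Optional extras: exact segmental duplications (for redundancy statistics)
and substitution-diverged genome pairs (for ANI).

Every generator is deterministic under a fixed seed; one RNG stream drives
a full :func:`run_simulation`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .genome_io import (
    GeneModel,
    GenomeSequence,
    HitRecord,
    ValidationError,
    write_fasta,
    write_gff,
    write_hits,
    write_ortholog_map,
)

SELF_LINEAGE = (
    "Bacteria",
    "Bacteroidetes",
    "Cytophagia",
    "Cytophagales",
    "Amoebophilaceae",
    "Cardinium",
)

#: donor-taxon leaf label -> (group weight key, lineage)
DONOR_TAXA: dict[str, tuple[str, ...]] = {
    "Wolbachia|wSim": ("Bacteria", "Proteobacteria", "Alphaproteobacteria", "Rickettsiales", "Anaplasmataceae", "Wolbachia"),
    "Rickettsia|prowazekii": ("Bacteria", "Proteobacteria", "Alphaproteobacteria", "Rickettsiales", "Rickettsiaceae", "Rickettsia"),
    "Escherichia|coli": ("Bacteria", "Proteobacteria", "Gammaproteobacteria", "Enterobacterales", "Enterobacteriaceae", "Escherichia"),
    "Bacillus|subtilis": ("Bacteria", "Firmicutes", "Bacilli", "Bacillales", "Bacillaceae", "Bacillus"),
    "Chloroflexus|aurantiacus": ("Bacteria", "Chloroflexi", "Chloroflexia", "Chloroflexales", "Chloroflexaceae", "Chloroflexus"),
    "Streptomyces|coelicolor": ("Bacteria", "Actinobacteria", "Actinomycetia", "Streptomycetales", "Streptomycetaceae", "Streptomyces"),
}

#: donor-group label -> member donor taxa (nested groups overlap deliberately)
DONOR_GROUPS: dict[str, frozenset[str]] = {
    "Proteobacteria": frozenset({"Wolbachia|wSim", "Rickettsia|prowazekii", "Escherichia|coli"}),
    "Wolbachia": frozenset({"Wolbachia|wSim"}),
    "Rickettsia": frozenset({"Rickettsia|prowazekii"}),
    "Firmicutes": frozenset({"Bacillus|subtilis"}),
    "Chloroflexi": frozenset({"Chloroflexus|aurantiacus"}),
    "Actinobacteria": frozenset({"Streptomyces|coelicolor"}),
}

# donor mix for alien genes: ~64% Proteobacteria, half of those Wolbachia
_DONOR_CHOICES = (
    ("Wolbachia|wSim", 0.32),
    ("Rickettsia|prowazekii", 0.16),
    ("Escherichia|coli", 0.16),
    ("Bacillus|subtilis", 0.18),
    ("Chloroflexus|aurantiacus", 0.09),
    ("Streptomyces|coelicolor", 0.09),
)

_BACTEROIDETES_SUBJECTS = (
    "Amoebophilus|asiaticus",
    "Cytophaga|hutchinsonii",
    "Flavobacterium|johnsoniae",
    "Leadbetterella|byssophila",
    "Marivirga|tractuosa",
)


@dataclass(frozen=True)
class DuplicationConfig:
    """Append exact copies of an internal segment, padding to ``target_len`` first."""

    segment_len: int
    n_copies: int = 2
    target_len: int | None = None


@dataclass(frozen=True)
class SimConfig:
    """Study-condition defaults: 795 genes of which ~5% alien, ~39% GC, ~76% coding."""

    seed: int = 0
    n_native: int = 755
    n_alien: int = 40
    gene_len_range: tuple[int, int] = (300, 1800)  # bp, multiples of 3 enforced
    gc1: float = 0.47
    gc2: float = 0.37
    gc3: float = 0.33
    alien_shift: float | None = None  # absolute shift of the gene-total GC target
    alien_shift_delta: float = 3.0  # shift in units of the expected per-gene delta
    intergenic_len_range: tuple[int, int] = (150, 520)
    fraction_transposase: float = 0.375
    fraction_ancient: float = 0.475
    duplication: DuplicationConfig | None = None
    max_genome_len: int = 5_000_000
    genome_id: str = "sim_chromosome"

    def __post_init__(self) -> None:
        if self.n_native < 0 or self.n_alien < 0:
            raise ValidationError("gene counts must be non-negative")
        for frac in (self.gc1, self.gc2, self.gc3):
            if not (0.0 < frac < 1.0):
                raise ValidationError("GC targets must lie in (0, 1)")

    @property
    def mean_gene_len(self) -> float:
        return (self.gene_len_range[0] + self.gene_len_range[1]) / 2.0

    @property
    def gct_target(self) -> float:
        return (self.gc1 + self.gc2 + self.gc3) / 3.0

    @property
    def expected_delta_t(self) -> float:
        """Analytic per-gene sd of total GC for a native gene of mean length."""
        p = self.gct_target
        return float(np.sqrt(p * (1 - p) / self.mean_gene_len))

    @property
    def gct_shift(self) -> float:
        """Alien shift of the gene-total GC target (absolute wins over delta units)."""
        if self.alien_shift is not None:
            return self.alien_shift
        return self.alien_shift_delta * self.expected_delta_t


@dataclass
class SimResult:
    genome: GenomeSequence
    genes: list[GeneModel]
    truth: pd.DataFrame
    duplication_intervals: tuple[tuple[int, int], ...]
    config: SimConfig


_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _random_dna(rng: np.random.Generator, length: int, gc: float) -> str:
    is_gc = rng.random(length) < gc
    second = rng.random(length) < 0.5
    # GC -> G or C; AT -> A or T
    codes = np.where(is_gc, np.where(second, 2, 1), np.where(second, 0, 3))
    return _BASES[codes].tobytes().decode("ascii")


def _random_gene(rng: np.random.Generator, length: int, gc_targets: tuple[float, float, float]) -> str:
    probs = np.tile(np.asarray(gc_targets), length // 3)
    is_gc = rng.random(length) < probs
    second = rng.random(length) < 0.5
    codes = np.where(is_gc, np.where(second, 2, 1), np.where(second, 0, 3))
    return _BASES[codes].tobytes().decode("ascii")


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def simulate_genome(config: SimConfig, rng: np.random.Generator | None = None) -> SimResult:
    """Generate genome FASTA content, gene models and the ground-truth table."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n_genes = config.n_native + config.n_alien
    statuses = np.array(["native"] * config.n_native + ["alien"] * config.n_alien)
    rng.shuffle(statuses)

    shift = config.gct_shift
    alien_targets = (
        float(np.clip(config.gc1 + 1.5 * shift, 0.02, 0.98)),
        config.gc2,
        float(np.clip(config.gc3 + 1.5 * shift, 0.02, 0.98)),
    )
    native_targets = (config.gc1, config.gc2, config.gc3)

    lo, hi = (config.gene_len_range[0] // 3, config.gene_len_range[1] // 3)
    pieces: list[str] = []
    genes: list[GeneModel] = []
    rows: list[dict] = []
    pos = 0
    width = max(4, len(str(n_genes)))
    for i, status in enumerate(statuses, 1):
        spacer_len = int(rng.integers(config.intergenic_len_range[0], config.intergenic_len_range[1] + 1))
        pieces.append(_random_dna(rng, spacer_len, config.gct_target))
        pos += spacer_len
        length = int(rng.integers(lo, hi + 1)) * 3
        targets = alien_targets if status == "alien" else native_targets
        cds = _random_gene(rng, length, targets)
        strand = "+" if i % 2 == 1 else "-"
        pieces.append(cds if strand == "+" else _revcomp(cds))
        gene_id = f"g{i:0{width}d}"
        genes.append(
            GeneModel(gene_id=gene_id, contig=config.genome_id, start=pos + 1, end=pos + length, strand=strand)
        )
        pos += length
        is_alien = status == "alien"
        donor = None
        if is_alien:
            labels = [t for t, _ in _DONOR_CHOICES]
            weights = np.array([w for _, w in _DONOR_CHOICES])
            donor = str(rng.choice(labels, p=weights / weights.sum()))
        rows.append(
            {
                "gene_id": gene_id,
                "status": status,
                "donor_taxon": donor or "",
                "is_transposase": bool(is_alien and rng.random() < config.fraction_transposase),
                "ancient": bool(is_alien and rng.random() < config.fraction_ancient),
                "start": pos - length + 1,
                "end": pos,
                "strand": strand,
                "length_bp": length,
            }
        )
    tail = int(rng.integers(config.intergenic_len_range[0], config.intergenic_len_range[1] + 1))
    pieces.append(_random_dna(rng, tail, config.gct_target))
    seq = "".join(pieces)

    dup_intervals: tuple[tuple[int, int], ...] = ()
    if config.duplication is not None:
        dup = config.duplication
        extra = dup.segment_len * (dup.n_copies - 1)
        if dup.target_len is not None:
            base_len = dup.target_len - extra
            if base_len < len(seq) or base_len < dup.segment_len:
                raise ValidationError(
                    f"duplication target_len {dup.target_len} too small for base genome of {len(seq)} bp"
                )
            seq += _random_dna(rng, base_len - len(seq), config.gct_target)
        src = int(rng.integers(0, len(seq) - dup.segment_len + 1))
        segment = seq[src : src + dup.segment_len]
        intervals = [(src + 1, src + dup.segment_len)]
        for _ in range(dup.n_copies - 1):
            start = len(seq)
            seq += segment
            intervals.append((start + 1, start + dup.segment_len))
        dup_intervals = tuple(intervals)

    if len(seq) > config.max_genome_len:
        raise ValidationError(f"simulated genome ({len(seq)} bp) exceeds max {config.max_genome_len} bp")
    truth = pd.DataFrame(
        rows,
        columns=[
            "gene_id", "status", "donor_taxon", "is_transposase",
            "ancient", "start", "end", "strand", "length_bp",
        ],
    )
    return SimResult(
        genome=GenomeSequence(id=config.genome_id, seq=seq),
        genes=genes,
        truth=truth,
        duplication_intervals=dup_intervals,
        config=config,
    )


def _loguniform(rng: np.random.Generator, lo_exp: float, hi_exp: float) -> float:
    return float(10.0 ** rng.uniform(lo_exp, hi_exp))


def simulate_hits(
    truth: pd.DataFrame,
    rng: np.random.Generator,
    sister_genomes: tuple[str, ...] = ("cEper1", "cBtQ1"),
    n_top: int = 10,
) -> list[HitRecord]:
    """Hit tables consistent with the truth labels.

    Native genes get Bacteroidetes top hits (plus, sometimes, a sister-strain
    hit that the screen must exclude); alien genes get their donor group's
    lineage across the whole top-10.  Every gene also receives sub-cutoff
    junk hits so the filters have something to reject.
    """
    hits: list[HitRecord] = []
    for row in truth.itertuples(index=False):
        alien = row.status == "alien"
        if alien:
            donor = row.donor_taxon
            lineage = DONOR_TAXA[donor]
            subjects = [donor] + [f"{donor.split('|')[0]}|sp{j}" for j in range(1, n_top)]
            lineages = [lineage] * n_top
        else:
            subjects = [_BACTEROIDETES_SUBJECTS[j % len(_BACTEROIDETES_SUBJECTS)] + f".{j}" for j in range(n_top)]
            lineages = [SELF_LINEAGE + (s.split("|")[0],) for s in subjects]
        base_bits = rng.uniform(380, 460)
        for j, (subject, lin) in enumerate(zip(subjects, lineages)):
            hits.append(
                HitRecord(
                    query_id=row.gene_id,
                    subject_id=subject,
                    pct_identity=float(rng.uniform(55, 95)),
                    aln_len=int(row.length_bp // 3),
                    evalue=_loguniform(rng, -80, -20),
                    bitscore=base_bits - 12 * j,
                    query_coverage=float(rng.uniform(78, 100)),
                    lineage=lin,
                )
            )
        if not alien and rng.random() < 0.4:
            # sister-strain hit: outranks everything but must be excluded
            sister = sister_genomes[int(rng.integers(0, len(sister_genomes)))]
            hits.append(
                HitRecord(
                    query_id=row.gene_id,
                    subject_id=f"{sister}|{row.gene_id}",
                    pct_identity=float(rng.uniform(80, 99)),
                    aln_len=int(row.length_bp // 3),
                    evalue=_loguniform(rng, -120, -80),
                    bitscore=base_bits + 100,
                    query_coverage=float(rng.uniform(90, 100)),
                    lineage=SELF_LINEAGE + (sister,),
                )
            )
        # junk below each cutoff in turn
        junk_lineage = DONOR_TAXA["Escherichia|coli"]
        hits.append(
            HitRecord(
                query_id=row.gene_id, subject_id="junk|low_identity", pct_identity=30.0,
                aln_len=50, evalue=1e-30, bitscore=60.0, query_coverage=90.0, lineage=junk_lineage,
            )
        )
        hits.append(
            HitRecord(
                query_id=row.gene_id, subject_id="junk|low_coverage", pct_identity=70.0,
                aln_len=30, evalue=1e-30, bitscore=55.0, query_coverage=20.0, lineage=junk_lineage,
            )
        )
    return hits


def simulate_orthologs(
    truth: pd.DataFrame,
    rng: np.random.Generator,
    sister_genomes: tuple[str, ...] = ("cEper1", "cBtQ1"),
) -> dict[str, frozenset[str]]:
    """Ortholog presence consistent with the ancient/recent truth labels."""
    mapping: dict[str, frozenset[str]] = {}
    for row in truth.itertuples(index=False):
        if row.status == "alien":
            if row.ancient:
                k = int(rng.integers(1, len(sister_genomes) + 1))
                labels = frozenset(rng.choice(sister_genomes, size=k, replace=False).tolist())
            else:
                labels = frozenset()
        else:
            labels = frozenset(sister_genomes) if rng.random() < 0.9 else frozenset({sister_genomes[0]})
        mapping[row.gene_id] = labels
    return mapping


def simulate_trees(truth: pd.DataFrame) -> dict[str, str]:
    """Per-alien-gene Newick strings placing the donor as the nearest neighbor."""
    trees: dict[str, str] = {}
    for row in truth.itertuples(index=False):
        if row.status != "alien":
            continue
        donor = row.donor_taxon
        trees[row.gene_id] = (
            f"(({row.gene_id}:0.05,'{donor}':0.05):0.10,"
            f"('Amoebophilus|asiaticus':0.05,'Cytophaga|hutchinsonii':0.05):0.10);"
        )
    return trees


def simulate_pair(seq: str, rate: float, rng: np.random.Generator | int) -> str:
    """Copy with iid substitutions (to a different base) at probability ``rate``."""
    if not (0.0 <= rate < 0.25):
        raise ValidationError("substitution rate must be in [0, 0.25)")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    arr = np.frombuffer(seq.encode("ascii"), dtype="S1").copy()
    subst = (rng.random(arr.size) < rate) & (arr != b"N")
    idx = np.flatnonzero(subst)
    lut = np.zeros(256, dtype=np.int64)
    for code, base in enumerate(b"ACGT"):
        lut[base] = code
    codes = lut[arr[idx].view(np.uint8)]
    # shift by 1..3 mod 4 guarantees a different base
    new_codes = (codes + rng.integers(1, 4, size=idx.size)) % 4
    arr[idx] = _BASES[new_codes]
    return arr.tobytes().decode("ascii")


_AA = np.frombuffer(b"ACDEFGHIKLMNPQRSTVWY", dtype="S1")


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return _AA[rng.integers(0, 20, size=length)].tobytes().decode("ascii")


def _mutate_protein(rng: np.random.Generator, seq: str, rate: float = 0.05) -> str:
    arr = np.frombuffer(seq.encode("ascii"), dtype="S1").copy()
    idx = np.flatnonzero(rng.random(arr.size) < rate)
    arr[idx] = _AA[rng.integers(0, 20, size=idx.size)]
    return arr.tobytes().decode("ascii")


def simulate_proteomes(
    rng: np.random.Generator | int,
    genomes: tuple[str, ...] = ("cSfur", "cEper1", "cBtQ1"),
    n_core: int = 15,
    n_shared: int = 6,
    n_specific: int = 9,
    len_range: tuple[int, int] = (80, 200),
) -> tuple[dict[tuple[str, str], str], dict[str, int]]:
    """Protein families with a known core/shared/specific composition.

    Family members are ~95%-identical copies of a family seed, so clustering
    at 50% identity / 70% coverage must recover the planted partition.
    Returns (proteins keyed by (genome, gene_id), expected cluster counts).
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    proteins: dict[tuple[str, str], str] = {}
    counter = {g: 0 for g in genomes}

    def add(genome: str, seq: str) -> None:
        counter[genome] += 1
        proteins[(genome, f"p{counter[genome]:04d}")] = seq

    for _ in range(n_core):
        seed_seq = _random_protein(rng, int(rng.integers(*len_range)))
        for g in genomes:
            add(g, _mutate_protein(rng, seed_seq))
    pairs = [(a, b) for i, a in enumerate(genomes) for b in genomes[i + 1 :]]
    for i in range(n_shared):
        seed_seq = _random_protein(rng, int(rng.integers(*len_range)))
        a, b = pairs[i % len(pairs)]
        add(a, _mutate_protein(rng, seed_seq))
        add(b, _mutate_protein(rng, seed_seq))
    for i in range(n_specific):
        add(genomes[i % len(genomes)], _random_protein(rng, int(rng.integers(*len_range))))
    expected = {"core": n_core, "shared": n_shared, "specific": n_specific}
    return proteins, expected


# free-living baseline weights per COG category, loosely shaped like a
# generalist heterotroph; host-dependent genomes inflate the retained
# information-processing categories and deflate the metabolic ones.
_FREE_WEIGHTS = {
    "J": 6.7, "K": 6.0, "L": 4.7, "B": 0.05, "C": 5.7, "G": 7.2, "E": 9.0,
    "F": 2.7, "H": 4.5, "I": 3.9, "P": 5.2, "Q": 2.5, "D": 0.8, "V": 2.2,
    "T": 3.6, "M": 7.2, "N": 0.2, "Z": 0.02, "U": 1.2, "O": 3.9, "R": 14.5, "S": 8.4,
}
_HOST_FACTORS = {
    "J": 3.2, "L": 2.8, "D": 2.5, "O": 1.5, "U": 2.0, "M": 1.0, "I": 1.0, "Z": 0.0,
    "B": 0.0, "C": 0.75, "E": 0.5, "F": 0.9, "G": 0.33, "H": 0.45, "K": 0.65,
    "N": 0.5, "P": 0.5, "Q": 0.5, "R": 0.85, "S": 0.55, "T": 0.3, "V": 0.9,
}


def simulate_cog_assignments(
    rng: np.random.Generator | int,
    n_host: int = 4,
    n_free: int = 13,
    clusters_host: int = 500,
    clusters_free: int = 2500,
    multi_letter_frac: float = 0.05,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Cluster-to-COG tables for two genome groups with a planted group effect."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    cats = list(_FREE_WEIGHTS)
    free_w = np.array([_FREE_WEIGHTS[c] for c in cats])
    host_w = np.array([_FREE_WEIGHTS[c] * _HOST_FACTORS[c] for c in cats])
    rows = []
    groups: dict[str, str] = {}
    specs = [(f"host{i:02d}", host_w, clusters_host, "host-dependent") for i in range(1, n_host + 1)]
    specs += [(f"free{i:02d}", free_w, clusters_free, "free-living") for i in range(1, n_free + 1)]
    for genome, weights, n_clusters, group in specs:
        groups[genome] = group
        draws = rng.choice(cats, size=n_clusters, p=weights / weights.sum())
        for c, letter in enumerate(draws, 1):
            letters = letter
            if rng.random() < multi_letter_frac:
                other = str(rng.choice([x for x in cats if x != letter]))
                letters = letter + other
            rows.append({"genome": genome, "cluster_id": f"{genome}_c{c:05d}", "cog_letters": letters})
    return pd.DataFrame(rows), groups


def run_simulation(config: SimConfig, out_dir: str | Path) -> SimResult:
    """Generate a full input set under one RNG stream and write every dialect.

    Emits genome.fasta, genes.gff3, hits.tsv, orthologs.tsv, truth.tsv and
    trees/<gene_id>.nwk under ``out_dir``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    sim = simulate_genome(config, rng)
    write_fasta([sim.genome], out / "genome.fasta")
    write_gff(sim.genes, out / "genes.gff3")
    hits = simulate_hits(sim.truth, rng)
    write_hits(hits, out / "hits.tsv")
    orthologs = simulate_orthologs(sim.truth, rng)
    write_ortholog_map(orthologs, out / "orthologs.tsv")
    trees = simulate_trees(sim.truth)
    tree_dir = out / "trees"
    tree_dir.mkdir(exist_ok=True)
    for gene_id, newick in trees.items():
        (tree_dir / f"{gene_id}.nwk").write_text(newick + "\n")
    transposases = sim.truth.loc[sim.truth.is_transposase, "gene_id"]
    (out / "transposases.txt").write_text("".join(f"{g}\n" for g in transposases))
    header = f"# seed={config.seed}\n"
    truth_path = out / "truth.tsv"
    with open(truth_path, "w") as fh:
        fh.write(header)
        sim.truth.to_csv(fh, sep="\t", index=False)
    if sim.duplication_intervals:
        with open(out / "duplications.tsv", "w") as fh:
            fh.write(header)
            for s, e in sim.duplication_intervals:
                fh.write(f"{s}\t{e}\n")
    return sim
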