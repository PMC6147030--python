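"""Stage orchestration and the paper-style summary report.

`run_pipeline` drives the single-genome stages over one input directory:
genome descriptives, the composition screen, the taxonomy screen, evidence
combination, donor/age assignment and optional redundancy/ANI, then writes
per-stage TSVs and one JSON summary.  All percentages in reports are
computed through :func:`pct` (two decimals), so a count ratio and its
printed percentage can never drift apart.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import composition_screen as comp
from . import genome_stats as stats
from . import taxonomy_screen as tax
from .genome_io import (
    ValidationError,
    read_fasta,
    read_gff,
    read_hits,
    read_ortholog_map,
)
from .synthetic import DONOR_GROUPS


def pct(count: float, total: float, digits: int = 2) -> float:
    """Report-formatting percentage: count/total x 100 rounded to ``digits``."""
    if total <= 0:
        raise ValidationError("percentage denominator must be positive")
    return round(count / total * 100.0, digits)


def format_scientific(p: float, sig: int = 3) -> str:
    """Scientific notation with ``sig`` significant digits, e.g. 8.40E-04."""
    return f"{p:.{sig - 1}e}".upper()


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass(frozen=True)
class RunConfig:
    """All inputs and thresholds of a pipeline run."""

    fasta: str = ""
    gff: str = ""
    hits: str = ""
    orthologs: str = ""
    trees_dir: str | None = None
    transposases: str | None = None  # one gene id per line; annotation input
    self_aln: str | None = None
    ani_against: str | None = None
    out_dir: str = "endoscan_out"
    seed: int = 0
    min_len_bp: int = 300
    k_delta: float = 1.5
    hit_min_identity: float = 50.0
    hit_max_evalue: float = 1e-5
    hit_min_coverage: float = 70.0
    n_top: int = 10
    self_group: str = "Bacteroidetes"
    exclude_subject_genomes: tuple[str, ...] = ("cEper1", "cBtQ1")
    cluster_min_identity: float = 50.0
    cluster_min_coverage: float = 70.0
    redundancy_min_identity: float = 95.0
    redundancy_max_evalue: float = 1e-20
    ani_fragment_len: int = 1020

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        if "exclude_subject_genomes" in raw:
            raw["exclude_subject_genomes"] = tuple(raw["exclude_subject_genomes"])
        return cls(**raw)


def _require(path: str | None, stage: str) -> Path:
    if not path or not Path(path).exists():
        raise StageError(f"stage '{stage}': required input missing: {path!r}")
    return Path(path)


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Run all applicable stages; returns the summary dict (also written as JSON)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- load & validate -------------------------------------------------
    fasta = _require(config.fasta, "load")
    gff = _require(config.gff, "load")
    genomes = read_fasta(fasta)
    genome = genomes[0]
    genes = read_gff(gff)
    if not genes:
        raise StageError("stage 'load': empty gene set")
    contig_len = {g.id: g.length_bp for g in genomes}
    for g in genes:
        if g.contig not in contig_len or g.end > contig_len[g.contig]:
            raise StageError(f"stage 'load': gene {g.gene_id!r} outside its contig")

    # --- genome descriptives --------------------------------------------
    total_len = sum(contig_len.values())
    mean_len = sum(g.length_bp for g in genes) / len(genes)
    summary: dict[str, Any] = {
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(config).items()},
        "genome": {
            "id": genome.id,
            "length_bp": total_len,
            "gc_pct": round(stats.gc_content(genome.seq), 2),
            "n_cds": len(genes),
            "mean_gene_length_bp": round(mean_len, 1),
            "coding_density_pct": pct(sum(g.length_bp for g in genes), total_len),
        },
    }

    # --- composition screen ---------------------------------------------
    profiles = comp.profiles_from_genome(genome, genes)
    model, calls = comp.screen_profiles(profiles, min_len_bp=config.min_len_bp, k=config.k_delta)
    comp_rows = []
    for p, c in zip(profiles, calls):
        d1, d2, d3, dT = c.deviations
        comp_rows.append(
            {
                "gene_id": p.gene_id, "length_bp": p.length_bp,
                "gc1": round(p.gc1, 4), "gc2": round(p.gc2, 4),
                "gc3": round(p.gc3, 4), "gct": round(p.gct, 4),
                "d1": round(d1, 4), "d2": round(d2, 4), "d3": round(d3, 4), "dT": round(dT, 4),
                "rule_total": c.rule_total, "rule_positions": c.rule_positions, "flagged": c.flagged,
            }
        )
    pd.DataFrame(comp_rows).to_csv(out / "composition.tsv", sep="\t", index=False)
    flags = {c.gene_id: c.flagged for c in calls}

    # --- taxonomy screen -------------------------------------------------
    hits_path = _require(config.hits, "taxonomy")
    hits_by_gene = read_hits(hits_path)
    tax_calls = tax.screen_hits(
        hits_by_gene,
        gene_universe=flags,
        min_identity=config.hit_min_identity,
        max_evalue=config.hit_max_evalue,
        min_coverage=config.hit_min_coverage,
        exclude_subject_genomes=config.exclude_subject_genomes,
        n_top=config.n_top,
        self_group=config.self_group,
    )
    pd.DataFrame(
        [
            {
                "gene_id": c.gene_id, "is_candidate": c.is_candidate,
                "n_qualified_hits": c.n_qualified_hits, "top_hits_examined": c.top_hits_examined,
            }
            for c in tax_calls
        ]
    ).to_csv(out / "taxonomy.tsv", sep="\t", index=False)

    # --- combine, donors, age --------------------------------------------
    candidates = tax.combine_evidence(flags, tax_calls)
    orthologs = read_ortholog_map(_require(config.orthologs, "age"))
    trees: dict[str, str] = {}
    if config.trees_dir and Path(config.trees_dir).is_dir():
        for f in sorted(Path(config.trees_dir).glob("*.nwk")):
            trees[f.stem] = f.read_text()
    candidates = tax.assign_donors_and_age(
        candidates, trees, orthologs, other_genomes=config.exclude_subject_genomes
    )
    tax_flags = {c.gene_id: c.is_candidate for c in tax_calls}
    pd.DataFrame(
        [
            {
                "gene_id": g, "composition_flag": flags[g], "taxonomy_flag": tax_flags[g],
                "candidate": g in {c.gene_id for c in candidates},
            }
            for g in sorted(flags)
        ]
    ).to_csv(out / "screen_calls.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {"gene_id": c.gene_id, "donor": c.donor_taxon or "", "age": c.age}
            for c in candidates
        ],
        columns=["gene_id", "donor", "age"],
    ).to_csv(out / "candidates.tsv", sep="\t", index=False)

    n_ancient = sum(1 for c in candidates if c.age == "ancient")
    n_recent = sum(1 for c in candidates if c.age == "recent")
    assert n_ancient + n_recent == len(candidates)
    transposase_genes: set[str] = set()
    if config.transposases and Path(config.transposases).exists():
        transposase_genes = {
            line.strip() for line in Path(config.transposases).read_text().splitlines() if line.strip()
        }
    donor_table = tax.donor_summary(candidates, DONOR_GROUPS, transposase_genes=transposase_genes)
    summary["hgt"] = {
        "n_flagged_composition": sum(flags.values()),
        "n_candidates_taxonomy": sum(1 for c in tax_calls if c.is_candidate),
        "n_candidates": len(candidates),
        "pct_candidates": pct(len(candidates), len(genes)),
        "n_ancient": n_ancient,
        "n_recent": n_recent,
        "donor_fractions": donor_table.to_dict(orient="records"),
    }
    donor_table.to_csv(out / "donor_summary.tsv", sep="\t", index=False)

    # --- optional redundancy / ANI ---------------------------------------
    if config.self_aln:
        alignments = stats.read_self_alignments(_require(config.self_aln, "redundancy"))
        red = stats.self_redundancy(
            alignments,
            genome_len=total_len,
            genome_id=genome.id,
            min_identity=config.redundancy_min_identity,
            max_evalue=config.redundancy_max_evalue,
        )
        summary["redundancy"] = {
            "covered_bp": red.covered_bp,
            "redundancy_pct": round(red.redundancy_pct, 2),
        }
    if config.ani_against:
        other = read_fasta(_require(config.ani_against, "ani"))[0]
        res = stats.ani(genome, other, fragment_len=config.ani_fragment_len)
        summary["ani"] = {
            "genome_a": res.genome_a, "genome_b": res.genome_b,
            "ani_pct": round(res.ani_pct, 2), "n_fragments_used": res.n_fragments_used,
        }

    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return summary
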