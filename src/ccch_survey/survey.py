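"""End-to-end survey orchestration and run configuration.

``run_survey`` chains the stages — motif scan and census, architecture
table, duplicate calling with Ka/Ks and molecular dating, optional
subfamily assignment, gene-structure and chromosome statistics — and writes
each result as a TSV artifact plus one machine-readable JSON summary.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from . import genestruct
from .duplication import (
    DuplicationConfig,
    DuplicatePair,
    call_duplicates,
    classify_pair,
    codon_align,
    estimate_age,
    is_duplicate,
    ng86,
    pair_similarity,
)
from .motifs import ScanConfig, build_census, detect_rrtzf, scan_nes, scan_protein
from .phylo import assign_subfamilies
from .records import CdsRecord, GeneModel, ProteinRecord

logger = logging.getLogger("ccch_survey")


@dataclass
class SurveyConfig:
    """Run configuration for the full survey."""

    scan: ScanConfig = field(default_factory=ScanConfig)
    duplication: DuplicationConfig = field(default_factory=DuplicationConfig)
    seed: int = 0
    out_dir: str = "survey_out"

    @classmethod
    def from_mapping(cls, values: Mapping[str, str]) -> "SurveyConfig":
        """Build a config from a flat key-value mapping (file or CLI).

        Recognized keys: scan.a_min/a_max/b_min/b_max/c_min/c_max,
        scan.policy, dup.min_cds_coverage, dup.min_protein_identity,
        dup.tandem_max_distance, dup.tandem_max_intervening, dup.clock_rate,
        seed, out_dir.
        """
        def geti(key: str, default: int) -> int:
            return int(values.get(key, default))

        def getf(key: str, default: float) -> float:
            return float(values.get(key, default))

        scan = ScanConfig(
            a_range=(geti("scan.a_min", 3), geti("scan.a_max", 17)),
            b_range=(geti("scan.b_min", 4), geti("scan.b_max", 10)),
            c_range=(geti("scan.c_min", 1), geti("scan.c_max", 5)),
            overlap_policy=values.get("scan.policy", "non_overlapping"),  # type: ignore[arg-type]
        )
        dup = DuplicationConfig(
            min_cds_coverage=getf("dup.min_cds_coverage", 0.70),
            min_protein_identity=getf("dup.min_protein_identity", 0.70),
            tandem_max_distance=geti("dup.tandem_max_distance", 100_000),
            tandem_max_intervening=geti("dup.tandem_max_intervening", 10),
            clock_rate=getf("dup.clock_rate", 1.5e-8),
        )
        return cls(scan=scan, duplication=dup,
                   seed=geti("seed", 0), out_dir=values.get("out_dir", "survey_out"))


def read_config_file(path: str | Path) -> dict[str, str]:
    """Parse a flat ``key = value`` config file ('#' starts a comment)."""
    out: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"config line without '=': {line!r}")
        key, value = line.split("=", 1)
        out[key.strip()] = value.strip()
    return out


def survey_duplicates(
    cds: Sequence[CdsRecord],
    proteins: Sequence[ProteinRecord],
    gene_models: Sequence[GeneModel],
    config: DuplicationConfig = DuplicationConfig(),
) -> list[DuplicatePair]:
    """All-vs-all duplicate calling with classification, Ka/Ks, and ages.

    CDS and proteins are matched by ``gene_id`` (falling back to record id).
    A called pair missing its CDS keeps its similarity row with Ka/Ks fields
    absent (and a warning), rather than being dropped.
    """
    prot_by_gene = {p.gene_id or p.id: p for p in proteins}
    cds_by_gene = {c.gene_id or c.id: c for c in cds}
    models_by_gene = {m.gene_id: m for m in gene_models}
    by_chrom: dict[str, list[GeneModel]] = {}
    for m in sorted(gene_models, key=lambda g: (g.chromosome, g.start)):
        by_chrom.setdefault(m.chromosome, []).append(m)

    genes = sorted(set(cds_by_gene) & set(prot_by_gene))
    sims = []
    for i, ga in enumerate(genes):
        for gb in genes[i + 1:]:
            sims.append(
                pair_similarity(cds_by_gene[ga], cds_by_gene[gb],
                                prot_by_gene[ga], prot_by_gene[gb])
            )
    groups = call_duplicates(sims, config)
    group_of: dict[str, int] = {}
    for gid, group in enumerate(groups, 1):
        for gene in group:
            group_of[gene] = gid
    family = frozenset(g for group in groups for g in group)

    pairs: list[DuplicatePair] = []
    for sim in sims:
        if not is_duplicate(sim, config):
            continue
        ga, gb = sim.gene_a, sim.gene_b
        ma, mb = models_by_gene.get(ga), models_by_gene.get(gb)
        if ma is not None and mb is not None:
            dup_class = classify_pair(ma, mb, by_chrom.get(ma.chromosome, []), family, config)
        else:
            dup_class = "segmental"
            logger.warning("pair %s-%s: missing gene model, classified segmental", ga, gb)
        kaks = None
        age = None
        if ga in cds_by_gene and gb in cds_by_gene:
            row_a, row_b = codon_align(cds_by_gene[ga], cds_by_gene[gb],
                                       prot_by_gene[ga], prot_by_gene[gb])
            kaks = ng86(row_a, row_b)
            if not kaks.saturated:
                age = estimate_age(kaks.Ks, config.clock_rate)
        else:
            logger.warning("pair %s-%s: CDS missing, Ka/Ks not computed", ga, gb)
        pairs.append(
            DuplicatePair(gene_a=ga, gene_b=gb, similarity=sim,
                          duplication_class=dup_class, kaks=kaks, age_mya=age,
                          group_id=group_of[ga])
        )
    return pairs


def pairs_frame(pairs: Sequence[DuplicatePair]) -> pd.DataFrame:
    rows = []
    for p in pairs:
        rows.append(
            (p.gene_a, p.gene_b, p.similarity.cds_coverage, p.similarity.protein_identity,
             p.duplication_class,
             p.kaks.Ka if p.kaks else None, p.kaks.Ks if p.kaks else None,
             p.kaks.omega if p.kaks else None, p.age_mya, p.group_id)
        )
    return pd.DataFrame(
        rows,
        columns=["gene_a", "gene_b", "coverage", "identity", "class",
                 "Ka", "Ks", "omega", "age_mya", "group_id"],
    )


def run_survey(
    proteins: Sequence[ProteinRecord],
    cds: Sequence[CdsRecord] = (),
    gene_models: Sequence[GeneModel] = (),
    config: SurveyConfig = SurveyConfig(),
    references: Optional[Sequence[ProteinRecord]] = None,
    reference_labels: Optional[dict[str, str]] = None,
    chromosome_lengths: Optional[dict[str, int]] = None,
) -> dict:
    """Run the full survey and write its artifact bundle.

    Deterministic given inputs and seed. Writes under ``config.out_dir``:
    hits.tsv, census.tsv, architecture.tsv, pairs.tsv, genestruct.tsv,
    chromosome_census.tsv, assignments.tsv (when references given), and
    summary.json. Returns the summary dict.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info("survey seed=%d proteins=%d", config.seed, len(proteins))

    scan_cfg = config.scan
    if scan_cfg.overlap_policy != "non_overlapping":
        scan_cfg = ScanConfig(scan_cfg.a_range, scan_cfg.b_range, scan_cfg.c_range,
                              "non_overlapping")
    all_hits = []
    arch_rows = []
    for protein in proteins:
        hits = scan_protein(protein, scan_cfg)
        all_hits.extend(hits)
        tzf = detect_rrtzf(protein, hits, scan_cfg)
        nes = scan_nes(protein)
        arch_rows.append(
            (protein.id, len(hits),
             ";".join(h.type_label for h in hits),
             tzf is not None,
             tzf.rr_motif_present if tzf else False,
             len(nes))
        )
    census = build_census(all_hits, include_proteins=[p.id for p in proteins])

    pd.DataFrame(
        [(h.protein_id, h.start, h.end, *h.spacers, h.type_label, h.subsequence)
         for h in all_hits],
        columns=["protein_id", "start", "end", "a", "b", "c", "type_label", "subsequence"],
    ).to_csv(out / "hits.tsv", sep="\t", index=False)
    pd.DataFrame(
        [("C-X%d-C-X%d-C-X%d-H" % t, n, census.fractions[t]) for t, n in
         sorted(census.counts.items(), key=lambda kv: -kv[1])],
        columns=["type", "count", "fraction"],
    ).to_csv(out / "census.tsv", sep="\t", index=False)
    architecture = pd.DataFrame(
        arch_rows,
        columns=["protein_id", "motif_count", "motif_types", "is_rr_tzf",
                 "rr_motif_present", "nes_count"],
    )
    architecture.to_csv(out / "architecture.tsv", sep="\t", index=False)

    pairs: list[DuplicatePair] = []
    if cds:
        pairs = survey_duplicates(cds, proteins, gene_models, config.duplication)
        pairs_frame(pairs).to_csv(out / "pairs.tsv", sep="\t", index=False)

    summary: dict = {
        "n_proteins": len(proteins),
        "motif_total": census.total,
        "motif_types": census.n_types,
        "copy_number_min": min(census.per_protein_copy_number.values(), default=0),
        "copy_number_max": max(census.per_protein_copy_number.values(), default=0),
        "n_duplicate_pairs": len(pairs),
        "n_duplicate_groups": len({p.group_id for p in pairs}),
        "n_tandem_pairs": sum(p.duplication_class == "tandem" for p in pairs),
    }

    if gene_models:
        table, exon_summary = genestruct.exon_stats(list(gene_models))
        table.to_csv(out / "genestruct.tsv", sep="\t", index=False)
        census_chrom = genestruct.chromosome_census(gene_models, chromosome_lengths)
        pd.DataFrame(
            [(c, census_chrom.counts[c], census_chrom.density_per_mb.get(c))
             for c in sorted(census_chrom.counts)],
            columns=["chromosome", "count", "density_per_mb"],
        ).to_csv(out / "chromosome_census.tsv", sep="\t", index=False)
        summary["exon_summary"] = exon_summary
        summary["chromosome_counts"] = census_chrom.counts
        summary["genes_placed"] = census_chrom.placed
        summary["genes_total"] = census_chrom.total

    if references and reference_labels:
        assignments = assign_subfamilies(list(proteins), list(references), reference_labels)
        pd.DataFrame(
            [(a.protein_id, a.subfamily, a.nearest_reference, a.distance)
             for a in assignments],
            columns=["protein_id", "subfamily", "nearest_ref", "distance"],
        ).to_csv(out / "assignments.tsv", sep="\t", index=False)
        summary["n_assigned"] = sum(a.subfamily != "ungrouped" for a in assignments)

    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
    return summary
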