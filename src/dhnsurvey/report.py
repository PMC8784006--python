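"""Survey tallies and end-to-end orchestration.

``tally_table`` reduces a per-gene survey table to the headline counts of a
gene-family survey: totals per species, per sub-genome (parsed from the
assigned names), per structural class and per family.  ``run_survey`` chains
the stages — gene-set ingest, segment scan and typing, properties, tandem
screen, homoeolog grouping/naming/auditing, promoter elements, SSRs and
expression calls — and writes one TSV per stage plus a JSON summary.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import re
from collections import Counter
from pathlib import Path

import pandas as pd

from . import expression as expr
from . import homoeologs as hom
from . import motifs
from . import promoter_ssr as prom
from . import tandem as td
from .config import DEFAULT_CONFIG, Config
from .core import (
    SPECIES_SUBGENOMES,
    read_gene_set,
    write_survey_table,
)
from .properties import compute_properties

logger = logging.getLogger(__name__)

_NAME_RE = re.compile(r"^([A-Za-z]+?)DHN(\d+)(?:-([A-D]?)(\d*))?$")


def parse_gene_name(
    name: str, expected_slots=SPECIES_SUBGENOMES
) -> tuple[str, int, str | None, int | None] | None:
    """Split a survey name into (species, family, subgenome, ordinal).

    Diploid names carry no sub-genome letter; it is filled in from the
    species' single sub-genome.  Returns ``None`` for unparseable names.
    """
    m = _NAME_RE.match(name)
    if not m:
        return None
    species, family, letter, ordinal = m.groups()
    subgenome = letter or None
    if subgenome is None and species in expected_slots:
        subs = expected_slots[species]
        if len(subs) == 1:
            subgenome = subs[0]
    return species, int(family), subgenome, int(ordinal) if ordinal else None


def tally_table(
    table: pd.DataFrame,
    reannotated: bool = True,
    expected_slots=SPECIES_SUBGENOMES,
) -> dict:
    """Headline counts of a survey table.

    Requires ``name`` and ``type`` columns; ``species`` is parsed from the
    name when absent.  With ``reannotated=True`` (default) a
    ``type_corrected`` column, where present and not ".", replaces the
    annotated type — this mirrors the manual re-annotation step of a curated
    survey, in which a mis-annotated member is counted under its corrected
    structure.  Unparseable names are tallied under ``unassigned``.
    """
    species_counts: Counter = Counter()
    subgenome_counts: Counter = Counter()
    class_counts: Counter = Counter()
    family_counts: Counter = Counter()
    unassigned = 0
    for _, row in table.iterrows():
        type_string = row["type"]
        if reannotated:
            corrected = row.get("type_corrected")
            if isinstance(corrected, str) and corrected not in (".", ""):
                type_string = corrected
        arch = motifs.classify_type_string(str(type_string))
        class_counts[arch.cls] += 1
        parsed = parse_gene_name(str(row["name"]), expected_slots)
        if parsed is None:
            unassigned += 1
            logger.warning("unparseable gene name %r", row["name"])
            continue
        species, family, subgenome, _ = parsed
        species_counts[species] += 1
        family_counts[(species, family)] += 1
        if subgenome:
            subgenome_counts[(species, subgenome)] += 1
    return {
        "n_genes": int(len(table)),
        "species": dict(species_counts),
        "subgenomes": {f"{sp}-{sg}": n for (sp, sg), n in subgenome_counts.items()},
        "classes": dict(class_counts),
        "families": {f"{sp}DHN{fam}": n for (sp, fam), n in family_counts.items()},
        "unassigned": unassigned,
    }


def run_survey(
    gff3,
    cds_fasta,
    proteins_fasta,
    outdir,
    genome=None,
    hits=None,
    tpm=None,
    config: Config = DEFAULT_CONFIG,
    contrasts: dict[str, str] | None = None,
) -> dict:
    """Run every applicable stage and write the report files into ``outdir``.

    Writes survey_table.tsv, tandems.tsv, homoeolog_matrix.tsv,
    missing_genes.tsv and, when the optional inputs are given,
    promoter_elements.tsv, ssrs.tsv and expression_calls.tsv, plus
    summary.json with all headline counts.  Returns the summary dict.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {}

    genes = read_gene_set(gff3, cds_fasta, proteins_fasta)
    if hits is not None:
        from .core import read_hit_table

        confirmed = motifs.screen_candidates(
            read_hit_table(hits), {g.gene_id: g.protein for g in genes}, config
        )
        genes = [g for g in genes if g.gene_id in confirmed]
        summary["screened_candidates"] = len(genes)

    architectures = {}
    for gene in genes:
        _, arch = motifs.is_dehydrin(gene.protein, config)
        architectures[gene.gene_id] = arch
    props = {g.gene_id: compute_properties(g.cds, g.protein) for g in genes}

    # homoeolog grouping first: it assigns the survey names
    similarity = hom.compute_similarity(genes, config)
    groups = hom.build_groups(genes, similarity, config)
    for gene in genes:
        if gene.chromosome in ("Un", "unknown", ""):
            hom.reassign_unplaced(gene, groups, similarity)
    names = hom.assign_names(groups)
    for gene in genes:
        gene.name = names.get(gene.gene_id, gene.gene_id)
    for group in groups:
        hom.infer_missing(group)
        hom.flag_anomalies(
            group, architectures, {g.gene_id: len(g.protein) for g in genes}
        )

    table = write_survey_table(
        genes,
        [architectures[g.gene_id] for g in genes],
        [props[g.gene_id] for g in genes],
        outdir / "survey_table.tsv",
    )

    calls, clusters = td.detect_tandems(genes, config)
    pd.DataFrame([dataclasses.asdict(c) for c in calls]).to_csv(
        outdir / "tandems.tsv", sep="\t", index=False
    )
    summary["tandem_clusters"] = [list(c) for c in clusters]

    matrix_rows = []
    missing_rows = []
    for group in groups:
        row: dict = {"family": group.family_index, "group_chromosome": group.homologous_group_chromosome}
        for (species, subgenome), members in sorted(group.slots.items()):
            row[f"{species}-{subgenome}"] = ",".join(names.get(m, m) for m in members)
        matrix_rows.append(row)
        for species, subgenome in group.missing_slots:
            missing_rows.append(
                {"family": group.family_index, "species": species, "subgenome": subgenome}
            )
    pd.DataFrame(matrix_rows).to_csv(
        outdir / "homoeolog_matrix.tsv", sep="\t", index=False, na_rep="."
    )
    pd.DataFrame(missing_rows, columns=["family", "species", "subgenome"]).to_csv(
        outdir / "missing_genes.tsv", sep="\t", index=False
    )
    summary["missing_slots"] = len(missing_rows)
    summary["flags"] = {
        name: flag for g in groups for name, flag in sorted(g.flags.items())
    }

    if genome is not None:
        import pyfaidx

        fasta = pyfaidx.Fasta(str(genome))
        element_rows = []
        ssr_rows = []
        for gene in genes:
            if gene.chromosome not in fasta:
                continue
            promoter = prom.extract_promoter(gene, fasta, config=config)
            for hit in prom.scan_elements(promoter):
                element_rows.append(
                    {"gene": gene.name, "element": hit.element_name,
                     "position": hit.position, "strand": hit.strand,
                     "matched_seq": hit.matched_seq}
                )
            for rec in prom.mine_ssrs(gene.cds, config=config):
                ssr_rows.append({"gene": gene.name, **dataclasses.asdict(rec)})
        pd.DataFrame(element_rows).to_csv(
            outdir / "promoter_elements.tsv", sep="\t", index=False
        )
        pd.DataFrame(ssr_rows).to_csv(outdir / "ssrs.tsv", sep="\t", index=False)
        summary["n_element_hits"] = len(element_rows)
        summary["n_ssrs"] = len(ssr_rows)

    if tpm is not None:
        matrix = pd.read_csv(tpm, sep="\t", index_col=0)
        calls_e = expr.call_matrix(matrix, contrasts, config)
        pd.DataFrame([dataclasses.asdict(c) for c in calls_e]).to_csv(
            outdir / "expression_calls.tsv", sep="\t", index=False
        )
        summary["bin_counts"] = {
            condition: expr.summarize_bins(matrix, condition, config)
            for condition in matrix.columns
        }
        summary["regulation_counts"] = dict(
            Counter(c.regulation for c in calls_e if c.regulation != "none")
        )

    summary.update(tally_table(table))
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
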