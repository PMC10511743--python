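"""TSV readers/writers for the pipeline's tabular interfaces."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd

from .catalog import GenomeCatalogEntry
from .hosts import SpacerHit, TaxonomyLineage
from .lysogeny import LysogenAlignment


def write_tsv(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=False)


def read_mapping(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_catalog(path) -> list[GenomeCatalogEntry]:
    """Catalog TSV: id, length_bp, circular, tools (comma list),
    integrase, source, host_lineage."""
    frame = pd.read_csv(path, sep="\t", keep_default_na=False)
    entries = []
    for _, row in frame.iterrows():
        tools = frozenset(
            t for t in str(row.get("tools", "")).split(",") if t and t != "nan"
        )
        entries.append(
            GenomeCatalogEntry(
                id=str(row["id"]),
                length_bp=int(row["length_bp"]),
                circular=bool(int(row.get("circular", 0))),
                tool_predictions=tools,
                integrase=bool(int(row.get("integrase", 0))),
                source=str(row.get("source", "virome")),
                host_lineage=str(row.get("host_lineage", "")),
            )
        )
    return entries


def write_catalog(entries: Iterable[GenomeCatalogEntry], path) -> None:
    rows = [
        {
            "id": e.id,
            "length_bp": e.length_bp,
            "circular": int(e.circular),
            "tools": ",".join(sorted(e.tool_predictions)),
            "integrase": int(e.integrase),
            "source": e.source,
            "host_lineage": e.host_lineage,
        }
        for e in entries
    ]
    write_tsv(pd.DataFrame(rows), path)


def read_spacer_hits(path) -> list[SpacerHit]:
    """Hits TSV mirroring tabular alignment output plus lineage columns."""
    frame = pd.read_csv(path, sep="\t", keep_default_na=False)
    hits = []
    for _, row in frame.iterrows():
        hits.append(
            SpacerHit(
                spacer_id=str(row["spacer_id"]),
                source=str(row["source"]),
                source_lineage=TaxonomyLineage.from_string(str(row["source_lineage"])),
                votu_id=str(row["votu_id"]),
                mismatches=int(row["mismatches"]),
                gaps=int(row["gaps"]),
                align_len=int(row["align_len"]),
                spacer_len=int(row["spacer_len"]),
                evalue=float(row.get("evalue", 0.0)),
            )
        )
    return hits


def write_spacer_hits(hits: Iterable[SpacerHit], path) -> None:
    rows = [
        {
            "spacer_id": h.spacer_id,
            "source": h.source,
            "source_lineage": h.source_lineage.to_string(),
            "votu_id": h.votu_id,
            "mismatches": h.mismatches,
            "gaps": h.gaps,
            "align_len": h.align_len,
            "spacer_len": h.spacer_len,
            "evalue": h.evalue,
        }
        for h in hits
    ]
    write_tsv(pd.DataFrame(rows), path)


def write_lysogen_alignments(alignments: Iterable[LysogenAlignment], path) -> None:
    rows = [
        {
            "votu_id": a.votu_id,
            "contig_id": a.contig_id,
            "pct_identity": a.pct_identity,
            "align_len": a.align_len,
            "evalue": a.evalue,
            "flank_len": a.flank_len,
        }
        for a in alignments
    ]
    write_tsv(pd.DataFrame(rows), path)


def read_lysogen_alignments(path) -> list[LysogenAlignment]:
    frame = pd.read_csv(path, sep="\t")
    return [
        LysogenAlignment(
            votu_id=str(r["votu_id"]),
            contig_id=str(r["contig_id"]),
            pct_identity=float(r["pct_identity"]),
            align_len=int(r["align_len"]),
            evalue=float(r["evalue"]),
            flank_len=int(r["flank_len"]),
        )
        for _, r in frame.iterrows()
    ]


def write_dataset(dataset, outdir) -> None:
    """Write every generated table of a synthetic scenario as TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_tsv(dataset.votu_catalog, outdir / "votu_catalog.tsv")
    write_tsv(dataset.mag_catalog, outdir / "mag_catalog.tsv")
    write_tsv(dataset.virome_records, outdir / "virome_mapping.tsv")
    write_tsv(dataset.metagenome_records, outdir / "metagenome_mapping.tsv")
    write_tsv(dataset.dna_yields, outdir / "dna_yields.tsv")
    write_tsv(dataset.viral_read_fraction, outdir / "viral_read_fraction.tsv")
    if dataset.fraction_records is not None:
        write_tsv(dataset.fraction_records, outdir / "fraction_records.tsv")
        write_tsv(dataset.fraction_abundance, outdir / "fraction_abundance.tsv")
        write_tsv(dataset.sip_records, outdir / "sip_mapping.tsv")
    if dataset.spacer_hits:
        write_spacer_hits(dataset.spacer_hits, outdir / "spacer_hits.tsv")
    if dataset.lysogen_alignments:
        write_lysogen_alignments(
            dataset.lysogen_alignments, outdir / "lysogen_alignments.tsv"
        )
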