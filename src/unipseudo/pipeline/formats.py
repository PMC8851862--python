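"""File format glue: FASTA, GFF3, and the pipeline's TSV artifacts.

All internal coordinates are 0-based half-open; GFF3 is converted through
``coords.to_gff3``/``from_gff3`` and nowhere else.
"""
from __future__ import annotations

import csv
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ..coords import Interval, from_gff3, to_gff3
from ..genetics import translate
from ..models import GeneModel, ReadSupportTrack, SyntenyBlock
from ..simulate.config import TruthRecord, TruthTable


class DataError(ValueError):
    """Malformed input data; message carries file and line when known."""


# ---------------------------------------------------------------- FASTA

def write_fasta(seqs: dict[str, str], path: Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def read_fasta(path: Path) -> dict[str, str]:
    try:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    except Exception as exc:  # pragma: no cover
        raise DataError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------- GFF3

def write_gff3(genes: list[GeneModel], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            span = g.span
            s1, e1 = to_gff3(span.start, span.end)
            attrs = ";".join(f"{k}={v}" for k, v in g.attributes().items() if v != "")
            fh.write(
                f"{g.chrom}\tunipseudo\tgene\t{s1}\t{e1}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id};{attrs}\n"
            )
            fh.write(
                f"{g.chrom}\tunipseudo\tmRNA\t{s1}\t{e1}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}.t1;Parent={g.gene_id}\n"
            )
            for i, ex in enumerate(g.exons, 1):
                xs, xe = to_gff3(ex.start, ex.end)
                for feat in ("exon", "CDS"):
                    fh.write(
                        f"{g.chrom}\tunipseudo\t{feat}\t{xs}\t{xe}\t.\t{g.strand}\t"
                        f"{'.' if feat == 'exon' else 0}\t"
                        f"ID={g.gene_id}.{feat}{i};Parent={g.gene_id}.t1\n"
                    )


def _parse_attrs(raw: str) -> dict[str, str]:
    out = {}
    for item in raw.strip().split(";"):
        if not item:
            continue
        k, _, v = item.partition("=")
        out[k] = v
    return out


def parse_gff3(path: Path, assembly: dict[str, str]) -> list[GeneModel]:
    """Reconstruct GeneModels; CDS/protein are re-extracted from the assembly."""
    gene_rows: dict[str, dict] = {}
    cds_rows: dict[str, list[Interval]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise DataError(f"{path}:{lineno}: expected 9 columns, got {len(cols)}")
            chrom, _, feat, s1, e1, _, strand, _, attrs_raw = cols
            try:
                start, end = from_gff3(int(s1), int(e1))
            except ValueError as exc:
                raise DataError(f"{path}:{lineno}: bad coordinates {s1},{e1}") from exc
            if start < 0 or end < start:
                raise DataError(f"{path}:{lineno}: invalid interval {s1}..{e1}")
            if chrom not in assembly:
                raise DataError(f"{path}:{lineno}: unknown sequence {chrom!r}")
            attrs = _parse_attrs(attrs_raw)
            if feat == "gene":
                gid = attrs.get("ID")
                if not gid:
                    raise DataError(f"{path}:{lineno}: gene without ID")
                gene_rows[gid] = {"chrom": chrom, "strand": strand, "attrs": attrs}
            elif feat == "CDS":
                parent = attrs.get("Parent", "")
                gid = parent.rsplit(".t1", 1)[0]
                cds_rows.setdefault(gid, []).append(Interval(chrom, start, end, strand))
    genes = []
    for gid, info in gene_rows.items():
        exons = sorted(cds_rows.get(gid, []), key=lambda iv: iv.start)
        if not exons:
            raise DataError(f"{path}: gene {gid} has no CDS features")
        cds = "".join(assembly[iv.chrom][iv.start : iv.end] for iv in exons)
        if info["strand"] == "-":
            from ..genetics import revcomp

            cds = revcomp(cds)
            exons = exons[::-1]
        protein = translate(cds)
        if protein.endswith("*"):
            protein = protein[:-1]
        a = info["attrs"]
        genes.append(
            GeneModel(
                gene_id=gid,
                chrom=info["chrom"],
                strand=info["strand"],
                exons=exons,
                protein=protein,
                cds=cds,
                predicted=a.get("predicted", "0") == "1",
                intronless_cdna=a.get("intronless_cdna", "0") == "1",
                tsl_level=int(a.get("tsl", "1")),
                has_ccds=a.get("ccds", "1") == "1",
                family=a.get("family", ""),
            )
        )
    return genes


# ---------------------------------------------------------------- TSV

def write_tsv(path: Path, header: list[str], rows: list[list]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(header)
        w.writerows(rows)


def read_tsv(path: Path) -> tuple[list[str], list[list[str]]]:
    with open(path) as fh:
        r = csv.reader(fh, delimiter="\t")
        rows = list(r)
    if not rows:
        return [], []
    return rows[0], rows[1:]


def write_synteny(blocks: list[SyntenyBlock], path: Path) -> None:
    write_tsv(
        path,
        ["gene_id", "ref_chrom", "ref_start", "ref_end",
         "query_chrom", "query_start", "query_end", "strand"],
        [
            [b.gene_id, b.ref.chrom, b.ref.start, b.ref.end,
             b.query.chrom, b.query.start, b.query.end, b.strand]
            for b in blocks
        ],
    )


def read_synteny(path: Path) -> dict[str, Interval]:
    _, rows = read_tsv(path)
    out = {}
    for r in rows:
        out[r[0]] = Interval(r[4], int(r[5]), int(r[6]), r[7])
    return out


def write_truth(truth: TruthTable, path: Path) -> None:
    rows = [
        [r["gene_id"], r["kind"], r["chrom"], r["start"], r["end"],
         r["codon_position"], r["size"], r["detail"]]
        for r in truth.to_rows()
    ]
    rows += [[gid, "fate", "", "", "", "", "", fate] for gid, fate in sorted(truth.fates.items())]
    rows += [[""] + ["error_site", c, s, e, "", "", ""] for c, s, e in truth.error_sites]
    write_tsv(path, ["gene_id", "kind", "chrom", "start", "end",
                     "codon_position", "size", "detail"], rows)


def read_truth(path: Path) -> TruthTable:
    truth = TruthTable()
    _, rows = read_tsv(path)
    for r in rows:
        gid, kind = r[0], r[1]
        if kind == "fate":
            truth.fates[gid] = r[7]
        elif kind == "error_site":
            truth.error_sites.append((r[2], int(r[3]), int(r[4])))
        else:
            truth.events.append(
                TruthRecord(
                    gid, kind, r[2],
                    int(r[3]) if r[3] else -1,
                    int(r[4]) if r[4] else -1,
                    int(r[5]) if r[5] else None,
                    int(r[6]) if r[6] else None,
                    r[7],
                )
            )
    return truth


def write_support(track: ReadSupportTrack, path: Path) -> None:
    rows = []
    for chrom, runs in track.runs.items():
        for start, end, depth, support in runs:
            rows.append([chrom, start, end, depth, support])
    write_tsv(path, ["chrom", "start", "end", "depth", "support"], rows)


def read_support(path: Path) -> ReadSupportTrack:
    track = ReadSupportTrack()
    _, rows = read_tsv(path)
    for chrom, start, end, depth, support in rows:
        track.runs.setdefault(chrom, []).append(
            (int(start), int(end), int(depth), int(support))
        )
    return track
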