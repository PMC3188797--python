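"""Readers and writers for the standard text formats the toolkit consumes.

Annotation comes in as GFF3 (1-based inclusive) or BED6/BED12 (0-based
half-open); internally everything is 0-based half-open.  Signal comes in as
bedGraph (probe mode: each record is a valued probe; read mode: each record
is one read interval) or plain BED reads.  Bin tensors round-trip through a
directory of per-bin TSV matrices plus a JSON manifest.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .binning import BinScheme, BinTensor, SignalTrack, TranscriptAnnotation

__all__ = [
    "read_gff3",
    "read_bed_annotation",
    "read_bedgraph",
    "read_bed_reads",
    "read_expression",
    "read_operons",
    "read_track_table",
    "write_tensor",
    "read_tensor",
]

_ATTR_RE = re.compile(r"(\w+)=([^;]+)")


def _gff3_attributes(field: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(field))


def read_gff3(
    path: str | Path,
    feature_types: tuple[str, ...] = ("mRNA",),
    role: str = "coding",
) -> list[TranscriptAnnotation]:
    """Read transcript records from GFF3.

    ``ID`` gives the transcript id; ``Parent`` (or, failing that, ``ID``)
    gives the gene id.  GFF3 start is converted from 1-based inclusive to
    0-based half-open.  For miRBase-style pre-miRNA files pass
    ``feature_types=("miRNA_primary_transcript", "pre_miRNA")`` and
    ``role="pre_mirna"``.
    """
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 9 or cols[2] not in feature_types:
                continue
            attrs = _gff3_attributes(cols[8])
            tid = attrs.get("ID") or attrs.get("Name")
            if tid is None:
                raise ValueError(f"GFF3 record without ID/Name: {line.strip()}")
            gid = attrs.get("Parent") or attrs.get("gene_id") or tid
            out.append(
                TranscriptAnnotation(
                    transcript_id=tid,
                    gene_id=gid,
                    chrom=cols[0],
                    strand=cols[6],
                    start=int(cols[3]) - 1,
                    end=int(cols[4]),
                    role=role,
                )
            )
    return out


def read_bed_annotation(path: str | Path, role: str = "coding") -> list[TranscriptAnnotation]:
    """Read BED6/BED12 transcript records (name column = transcript id)."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split()
            if len(cols) < 6:
                raise ValueError(f"BED annotation needs >= 6 columns: {line.strip()}")
            out.append(
                TranscriptAnnotation(
                    transcript_id=cols[3],
                    gene_id=cols[3],
                    chrom=cols[0],
                    strand=cols[5],
                    start=int(cols[1]),
                    end=int(cols[2]),
                    role=role,
                )
            )
    return out


def read_bedgraph(
    path: str | Path, feature_name: str, stage: str, assay: str = "probe"
) -> SignalTrack:
    """Read a bedGraph track as probes (valued) or reads (value ignored)."""
    intervals = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split()
            chrom, start, end = cols[0], int(cols[1]), int(cols[2])
            if assay == "probe":
                intervals.append((chrom, start, end, float(cols[3])))
            else:
                intervals.append((chrom, start, end))
    return SignalTrack(feature_name, stage, assay, intervals)


def read_bed_reads(path: str | Path, feature_name: str, stage: str) -> SignalTrack:
    """Read a plain BED file of read intervals (unit weight)."""
    return read_bedgraph(path, feature_name, stage, assay="read")


def read_expression(path: str | Path):
    """Read a transcript x stage RPKM table (TSV, first column = id)."""
    from .association import ExpressionTable

    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionTable(df)


def read_operons(path: str | Path) -> dict[str, list[str]]:
    """Read operons: TSV of operon_id <TAB> comma-separated ordered gene ids."""
    out: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            op_id, genes = line.rstrip("\n").split("\t")
            out[op_id] = [g for g in genes.split(",") if g]
    return out


def read_track_table(path: str | Path, stage: str | None = None) -> list[SignalTrack]:
    """Read a track manifest TSV: feature <TAB> stage <TAB> assay <TAB> path.

    Paths are resolved relative to the manifest's directory.  If ``stage`` is
    given only tracks from that stage are loaded.
    """
    base = Path(path).parent
    tracks = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            feature, trk_stage, assay, rel = line.rstrip("\n").split("\t")
            if stage is not None and trk_stage != stage:
                continue
            tracks.append(read_bedgraph(base / rel, feature, trk_stage, assay))
    return tracks


def write_tensor(tensor: BinTensor, outdir: str | Path) -> None:
    """Write a tensor as one TSV matrix per bin plus a JSON manifest.

    Floats are written with ``repr`` so the round trip is bit-stable; masked
    cells are written as ``NA``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "transcript_ids": tensor.transcript_ids,
        "feature_names": tensor.feature_names,
        "bin_labels": tensor.bin_labels,
        "scheme": {
            "flank_bp": tensor.scheme.flank_bp,
            "bin_width_bp": tensor.scheme.bin_width_bp,
            "anchors": list(tensor.scheme.anchors),
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    for k, label in enumerate(tensor.bin_labels):
        fname = outdir / f"bin_{label.replace(':', '_')}.tsv"
        with open(fname, "w") as fh:
            fh.write("transcript_id\t" + "\t".join(tensor.feature_names) + "\n")
            for i, tid in enumerate(tensor.transcript_ids):
                cells = [
                    "NA" if tensor.mask[i, j, k] else repr(float(tensor.values[i, j, k]))
                    for j in range(len(tensor.feature_names))
                ]
                fh.write(tid + "\t" + "\t".join(cells) + "\n")


def read_tensor(indir: str | Path) -> BinTensor:
    """Read a tensor written by :func:`write_tensor`."""
    indir = Path(indir)
    with open(indir / "manifest.json") as fh:
        manifest = json.load(fh)
    ids = manifest["transcript_ids"]
    features = manifest["feature_names"]
    labels = manifest["bin_labels"]
    scheme = BinScheme(
        flank_bp=manifest["scheme"]["flank_bp"],
        bin_width_bp=manifest["scheme"]["bin_width_bp"],
        anchors=tuple(manifest["scheme"]["anchors"]),
    )
    n, m, k = len(ids), len(features), len(labels)
    values = np.zeros((n, m, k))
    mask = np.zeros((n, m, k), dtype=bool)
    for kk, label in enumerate(labels):
        fname = indir / f"bin_{label.replace(':', '_')}.tsv"
        with open(fname) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            assert header[1:] == features
            for i, line in enumerate(fh):
                cells = line.rstrip("\n").split("\t")
                for j, cell in enumerate(cells[1:]):
                    if cell == "NA":
                        mask[i, j, kk] = True
                    else:
                        values[i, j, kk] = float(cell)
    return BinTensor(ids, features, values, mask, labels, scheme)
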