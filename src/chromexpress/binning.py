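"""Positional binning of chromatin signal around transcript anchors.

The genomic neighbourhood of each transcript is tiled with fixed-width bins
around two anchors, the transcription start site (TSS) and the transcription
termination site (TTS).  With the default scheme (4 kb flank, 100 bp bins)
each anchor carries 80 bins and each transcript 160.  Signal tracks — valued
probe intervals from tiling arrays, or read intervals from sequencing — are
aggregated per bin, yielding an n_transcripts x n_features x n_bins tensor
whose per-bin slices are the predictor matrices used downstream.

Coordinates are 0-based half-open throughout.  Bins are ordered 5'->3' in
transcript orientation: for a '-' strand transcript the upstream bins lie at
higher genomic coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TranscriptAnnotation",
    "BinScheme",
    "SignalTrack",
    "Bin",
    "BinTensor",
    "make_bins",
    "aggregate_probe_signal",
    "aggregate_read_signal",
    "build_tensor",
    "normalize_columns",
]

VALID_ROLES = ("coding", "operon_member", "pre_mirna")


@dataclass(frozen=True)
class TranscriptAnnotation:
    """A transcript (or operon gene, or pre-miRNA locus) with genomic anchors.

    ``start`` / ``end`` are 0-based half-open genomic coordinates.  The TSS is
    the 5'-most transcribed base in transcript orientation and the TTS the
    3'-most; for many annotations these are in fact the boundaries of the
    protein-coding region, which is accepted as the anchor proxy.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    role: str = "coding"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.end - self.start < 1:
            raise ValueError(
                f"degenerate transcript {self.transcript_id}: "
                f"[{self.start}, {self.end})"
            )
        if self.role not in VALID_ROLES:
            raise ValueError(f"unknown role {self.role!r}")

    @property
    def tss(self) -> int:
        """Anchor coordinate of the transcription start site."""
        return self.start if self.strand == "+" else self.end

    @property
    def tts(self) -> int:
        """Anchor coordinate of the transcription termination site."""
        return self.end if self.strand == "+" else self.start

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class BinScheme:
    """Symmetric fixed-width binning around the TSS and TTS anchors."""

    flank_bp: int = 4000
    bin_width_bp: int = 100
    anchors: tuple = ("TSS", "TTS")

    def __post_init__(self) -> None:
        if self.flank_bp % self.bin_width_bp != 0:
            raise ValueError("flank_bp must be a multiple of bin_width_bp")
        if self.flank_bp <= 0 or self.bin_width_bp <= 0:
            raise ValueError("flank_bp and bin_width_bp must be positive")

    @property
    def n_per_side(self) -> int:
        return self.flank_bp // self.bin_width_bp

    @property
    def bins_per_anchor(self) -> int:
        return 2 * self.n_per_side

    @property
    def total_bins(self) -> int:
        return len(self.anchors) * self.bins_per_anchor

    def labels(self) -> list[str]:
        """Canonical flattened bin order: per anchor, u<n>..u1 then d1..d<n>.

        "u1" is the bin immediately upstream of the anchor (0 to
        ``bin_width_bp`` nucleotides upstream), "d1" the bin immediately
        downstream.
        """
        n = self.n_per_side
        out = []
        for anchor in self.anchors:
            out.extend(f"{anchor}:u{k}" for k in range(n, 0, -1))
            out.extend(f"{anchor}:d{k}" for k in range(1, n + 1))
        return out


class Bin(NamedTuple):
    """One genomic bin: half-open interval plus its canonical label."""

    chrom: str
    start: int
    end: int
    label: str


def make_bins(t: TranscriptAnnotation, scheme: BinScheme | None = None) -> list[Bin]:
    """Tile the +/- flank windows around the TSS and TTS of one transcript.

    Returns ``scheme.total_bins`` half-open intervals in 5'->3' transcript
    order.  Bins may extend below genomic coordinate 0; such bins are fully
    masked during aggregation rather than clipped.
    """
    scheme = scheme or BinScheme()
    w = scheme.bin_width_bp
    n = scheme.n_per_side
    sgn = 1 if t.strand == "+" else -1
    bins: list[Bin] = []
    for anchor_name in scheme.anchors:
        anchor = t.tss if anchor_name == "TSS" else t.tts
        # offset k (in bins) from anchor, negative = upstream
        for k in list(range(-n, 0)) + list(range(1, n + 1)):
            if sgn == 1:
                lo = anchor + (k - 1) * w if k > 0 else anchor + k * w
            else:
                # upstream is at higher coordinates on '-'
                lo = anchor - k * w if k > 0 else anchor + (-k - 1) * w
            hi = lo + w
            side = "u" if k < 0 else "d"
            label = f"{anchor_name}:{side}{abs(k)}"
            bins.append(Bin(t.chrom, lo, hi, label))
    # reorder: u bins were generated u_n..u1 (k=-n..-1), d bins d1..d_n -- done
    return bins


@dataclass
class SignalTrack:
    """One chromatin feature at one developmental stage.

    ``assay='probe'``: intervals carry real values (tiling-array probes);
    ``assay='read'``: intervals are sequencing reads, value ignored
    (unit weight).
    """

    feature_name: str
    stage: str
    assay: str
    intervals: Sequence[tuple]  # (chrom, start, end[, value])
    _by_chrom: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.assay not in ("probe", "read"):
            raise ValueError(f"assay must be 'probe' or 'read', got {self.assay!r}")
        by_chrom: dict[str, list] = {}
        for rec in self.intervals:
            chrom, start, end = rec[0], int(rec[1]), int(rec[2])
            if end <= start:
                raise ValueError(
                    f"{self.feature_name}: zero/negative-length interval "
                    f"{chrom}:{start}-{end}"
                )
            value = float(rec[3]) if (self.assay == "probe" and len(rec) > 3) else 1.0
            if self.assay == "probe" and not np.isfinite(value):
                raise ValueError(f"{self.feature_name}: non-finite probe value")
            by_chrom.setdefault(chrom, []).append((start, end, value))
        for chrom, recs in by_chrom.items():
            arr = np.asarray(recs, dtype=float)
            order = np.argsort(arr[:, 0], kind="stable")
            arr = arr[order]
            self._by_chrom[chrom] = {
                "starts": arr[:, 0],
                "ends": arr[:, 1],
                "values": arr[:, 2],
                "mids": (arr[:, 0] + arr[:, 1]) / 2.0,
                "max_len": float(np.max(arr[:, 1] - arr[:, 0])),
            }
        # probe queries are by midpoint; keep a midpoint-sorted view
        for chrom, d in self._by_chrom.items():
            order = np.argsort(d["mids"], kind="stable")
            d["mids_sorted"] = d["mids"][order]
            d["values_by_mid"] = d["values"][order]

    def chroms(self) -> list[str]:
        return list(self._by_chrom)


def aggregate_probe_signal(
    track: SignalTrack, bins: Sequence[Bin]
) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin mean probe value; bins without probes (or below coord 0) masked.

    A probe is assigned to the single bin containing its midpoint
    (half-open: lo <= mid < hi), so no probe is double counted.
    Returns ``(values, mask)`` with ``mask=True`` marking missing bins.
    """
    if track.assay != "probe":
        raise ValueError("aggregate_probe_signal requires a probe-assay track")
    values = np.zeros(len(bins))
    mask = np.ones(len(bins), dtype=bool)
    for i, b in enumerate(bins):
        if b.start < 0:
            continue
        d = track._by_chrom.get(b.chrom)
        if d is None:
            continue
        lo = np.searchsorted(d["mids_sorted"], b.start, side="left")
        hi = np.searchsorted(d["mids_sorted"], b.end, side="left")
        if hi > lo:
            values[i] = float(np.mean(d["values_by_mid"][lo:hi]))
            mask[i] = False
    return values, mask


def aggregate_read_signal(
    track: SignalTrack, bins: Sequence[Bin]
) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin overlap-weighted read count.

    Each read contributes overlap_bp / read_length to every bin it touches, so
    a read fully inside one bin contributes exactly 1 and a read is conserved
    across any window that contains it.  Bins with no reads score 0 (absence
    of reads is itself signal); only bins below coordinate 0 are masked.
    """
    if track.assay != "read":
        raise ValueError("aggregate_read_signal requires a read-assay track")
    values = np.zeros(len(bins))
    mask = np.zeros(len(bins), dtype=bool)
    for i, b in enumerate(bins):
        if b.start < 0:
            mask[i] = True
            continue
        d = track._by_chrom.get(b.chrom)
        if d is None:
            continue
        # candidate reads: start < bin end and end > bin start
        lo = np.searchsorted(d["starts"], b.start - d["max_len"], side="left")
        hi = np.searchsorted(d["starts"], b.end, side="left")
        if hi <= lo:
            continue
        starts = d["starts"][lo:hi]
        ends = d["ends"][lo:hi]
        overlap = np.minimum(ends, b.end) - np.maximum(starts, b.start)
        keep = overlap > 0
        if np.any(keep):
            values[i] = float(np.sum(overlap[keep] / (ends - starts)[keep]))
    return values, mask


@dataclass
class BinTensor:
    """transcripts x features x bins tensor of aggregated signal.

    ``values[i, j, k]`` is transcript i, feature j, bin k (flattened canonical
    order, see :meth:`BinScheme.labels`); ``mask`` flags missing cells.
    """

    transcript_ids: list[str]
    feature_names: list[str]
    values: np.ndarray
    mask: np.ndarray
    bin_labels: list[str]
    scheme: BinScheme = field(default_factory=BinScheme)

    def __post_init__(self) -> None:
        n, m, k = self.values.shape
        if (
            n != len(self.transcript_ids)
            or m != len(self.feature_names)
            or k != len(self.bin_labels)
        ):
            raise ValueError("tensor dimensions inconsistent with id lists")
        if self.mask.shape != self.values.shape:
            raise ValueError("mask shape mismatch")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def bin_index(self, label: str) -> int:
        try:
            return self.bin_labels.index(label)
        except ValueError:
            raise KeyError(
                f"unknown bin label {label!r}; valid labels are "
                f"u{self.scheme.n_per_side}..u1, d1..d{self.scheme.n_per_side} "
                f"per anchor in {self.scheme.anchors}, e.g. 'TSS:u1'"
            ) from None

    def bin_matrix(self, label: str) -> pd.DataFrame:
        """The n x m predictor matrix A for one bin (masked cells NaN)."""
        k = self.bin_index(label)
        mat = self.values[:, :, k].copy()
        mat[self.mask[:, :, k]] = np.nan
        return pd.DataFrame(mat, index=self.transcript_ids, columns=self.feature_names)

    def feature_matrix(self, feature: str) -> pd.DataFrame:
        """The n x 160 bin-profile matrix of one feature (masked cells NaN)."""
        try:
            j = self.feature_names.index(feature)
        except ValueError:
            raise KeyError(f"unknown feature {feature!r}") from None
        mat = self.values[:, j, :].copy()
        mat[self.mask[:, j, :]] = np.nan
        return pd.DataFrame(mat, index=self.transcript_ids, columns=self.bin_labels)

    def subset_transcripts(self, ids: Iterable[str]) -> "BinTensor":
        ids = list(ids)
        pos = {t: i for i, t in enumerate(self.transcript_ids)}
        idx = [pos[t] for t in ids]
        return BinTensor(
            ids,
            list(self.feature_names),
            self.values[idx],
            self.mask[idx],
            list(self.bin_labels),
            self.scheme,
        )


def build_tensor(
    annotations: Sequence[TranscriptAnnotation],
    tracks: Sequence[SignalTrack],
    scheme: BinScheme | None = None,
) -> BinTensor:
    """Aggregate every track over every transcript's bins into one tensor."""
    scheme = scheme or BinScheme()
    ids = [t.transcript_id for t in annotations]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate transcript ids: {dupes}")
    features = [tr.feature_name for tr in tracks]
    if len(set(features)) != len(features):
        raise ValueError("duplicate feature names among tracks")
    if not tracks:
        raise ValueError("no signal tracks given")
    n, m, k = len(ids), len(features), scheme.total_bins
    values = np.zeros((n, m, k))
    mask = np.zeros((n, m, k), dtype=bool)
    for i, t in enumerate(annotations):
        bins = make_bins(t, scheme)
        for j, tr in enumerate(tracks):
            if tr.assay == "probe":
                v, msk = aggregate_probe_signal(tr, bins)
            else:
                v, msk = aggregate_read_signal(tr, bins)
            values[i, j] = v
            mask[i, j] = msk
    return BinTensor(ids, features, values, mask, scheme.labels(), scheme)


def normalize_columns(A: pd.DataFrame) -> pd.DataFrame:
    """Column-wise robust standardisation: (x - median) / sd, NaN-aware.

    Makes feature signals comparable before clustering.  The sd is the
    sample standard deviation (ddof=1) over unmasked entries.
    """
    out = A.copy().astype(float)
    for col in out.columns:
        x = out[col]
        ok = x.notna()
        if ok.sum() < 2:
            raise ValueError(f"column {col!r} has fewer than 2 unmasked values")
        sd = float(x[ok].std(ddof=1))
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"zero-variance feature column: {col!r}")
        out[col] = (x - float(x[ok].median())) / sd
    return out
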