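"""Synthetic annotation, signal and expression with known ground truth.

The generator emulates the statistical structure the rest of the toolkit
assumes: each chromatin feature f has a per-transcript latent activity
a_{t,f}; log expression is a signed linear combination of the (standardised)
activities plus optional multiplicative interaction terms and Gaussian
noise, and the bin-level signal of feature f is its spatial weight profile
w_f(bin) times the activity plus measurement noise:

    a_{t,f}  = sign_f * sqrt(r) * z_t + sqrt(1 - r) * u_{t,f}   (coupled f)
    g_t      = sum_f sign_f * beta_f * a_{t,f}  +  sum_{(i,j)} c_ij * a_i a_j
    e_t^s    = s_e * (rho_s * g_t/sd(g) + sqrt(1 - rho_s^2) * eta) + sigma_e * eps
    x_{t,f,b} = w_f(b) * a_{t,f} + Normal(0, sd_f)              (probe features)

The shared factor z (weight ``feature_redundancy`` r) emulates the strong
mutual correlation and partial redundancy of real histone marks: activating
marks correlate positively with each other and negatively with repressive
ones.  The sign of the signal-expression correlation inside a feature's
weighted window equals sign_f, the informative bins are exactly where w_f
is large, and the stage-coupling vector rho makes chromatin (tied to
stage 0) progressively less predictive of later stages.  Read-assay
features emit Poisson counts with log-rate proportional to w_f(b) * a.
RPKM is 2^(mu + e) - 1 clipped at 0.

Operon members beyond the first gene get chromatin decoupled from their
expression and systematically lower expression (two-fold for second genes,
three-fold for last).  Pre-miRNA loci follow the same signal -> expression
law as coding genes, with signal averaged over the ~100 nt locus.

All randomness flows from the single mandatory seed; the same seed gives
byte-identical serialised output.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .binning import (
    BinScheme,
    BinTensor,
    SignalTrack,
    TranscriptAnnotation,
    build_tensor,
    make_bins,
)
from .association import ExpressionTable

__all__ = [
    "FeatureSpec",
    "GeneratorSpec",
    "SyntheticDataset",
    "default_features",
    "generate",
    "generate_tensor",
    "worked_example_small",
]

DEFAULT_STAGES = ("EEMB", "L1", "L2", "L3", "L4", "adult")
DEFAULT_STAGE_COUPLING = (1.0, 0.85, 0.75, 0.65, 0.55, 0.45)


@dataclass
class FeatureSpec:
    """One chromatin feature's generative parameters.

    ``profile`` shapes the spatial weight w_f(bin): ``tss_bump`` /
    ``tts_bump`` are Gaussian bumps centred on ``center`` (a bin label),
    ``flat`` is constant across all bins, ``decay`` falls off exponentially
    downstream of the TSS, ``none`` is identically zero (a decoy feature).
    ``beta`` couples the feature's latent activity to expression with sign
    ``sign``; ``noise_sd`` is the per-bin measurement noise.  ``bimodal``
    draws the activity from a two-component mixture (separation
    ``bimodal_sep`` sd units) instead of a standard normal.
    """

    name: str
    sign: int = 1
    profile: str = "flat"
    center: str = "TSS:d1"
    bump_sd_bins: float = 4.0
    decay_bins: float = 20.0
    amplitude: float = 1.0
    beta: float = 1.0
    noise_sd: float = 0.7
    bimodal: bool = False
    bimodal_sep: float = 4.0
    assay: str = "probe"

    @property
    def coupled(self) -> bool:
        return self.beta != 0 and self.profile != "none"


def default_features() -> list[FeatureSpec]:
    """The default 16-feature panel emulating an early-embryo chromatin set.

    Promoter marks (H3K4me2/3) bump just upstream of the TSS, the K79
    methylations bump at the TSS and carry the strongest coupling, K36
    marks sit over the transcribed body, the repressive K9/K27 marks are
    flat and negatively coupled, polymerase (read assay) peaks after the
    TTS, and histone H3 plus the four X-inactivation factors are decoys
    with no coupling.
    """
    return [
        FeatureSpec("H3", profile="none", beta=0.0),
        FeatureSpec("H3K4me2", profile="tss_bump", center="TSS:u1", bump_sd_bins=2, beta=1.0),
        FeatureSpec("H3K4me3", profile="tss_bump", center="TSS:u1", bump_sd_bins=2, beta=1.0, bimodal=True),
        FeatureSpec("H3K9me2", sign=-1, profile="flat", amplitude=0.6, beta=0.8),
        FeatureSpec("H3K9me3", sign=-1, profile="flat", amplitude=0.6, beta=0.8),
        FeatureSpec("H3K27me3", sign=-1, profile="flat", amplitude=0.6, beta=0.6),
        FeatureSpec("H3K36me2", profile="decay", decay_bins=25, beta=0.8),
        FeatureSpec("H3K36me3", profile="flat", amplitude=0.8, beta=1.0, bimodal=True),
        FeatureSpec("H3K79me1", profile="tss_bump", center="TSS:d1", bump_sd_bins=2.5, beta=1.0),
        FeatureSpec("H3K79me2", profile="tss_bump", center="TSS:d1", bump_sd_bins=2.5, beta=1.2),
        FeatureSpec("H3K79me3", profile="tss_bump", center="TSS:d1", bump_sd_bins=2.5, beta=1.0),
        FeatureSpec("MES4", profile="none", beta=0.0),
        FeatureSpec("MRG1", profile="none", beta=0.0),
        FeatureSpec("SDC2", profile="none", beta=0.0),
        FeatureSpec("DPY27", profile="none", beta=0.0),
        FeatureSpec("POLII", profile="tts_bump", center="TTS:d1", bump_sd_bins=2.5, beta=0.8, assay="read"),
    ]


@dataclass
class GeneratorSpec:
    """Full description of one synthetic study."""

    seed: int
    n_transcripts: int = 2000
    features: list[FeatureSpec] = field(default_factory=default_features)
    stages: tuple = DEFAULT_STAGES
    stage_coupling: tuple = DEFAULT_STAGE_COUPLING
    feature_redundancy: float = 0.6  # weight r of the shared mark factor
    expr_mu: float = 3.5
    expr_scale: float = 2.5  # sd of the chromatin-explainable log2 expression
    expr_noise_sd: float = 1.25  # sd of the chromatin-independent residual
    interaction_pairs: list[tuple] = field(default_factory=list)  # (name_i, name_j, coeff)
    n_operons: int = 0
    operon_sizes: tuple = (2, 3, 4)
    n_mirnas: int = 0
    scheme: BinScheme = field(default_factory=BinScheme)
    transcript_length_range: tuple = (8200, 12000)
    chrom: str = "chrI"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if len(self.stage_coupling) != len(self.stages):
            raise ValueError(
                f"stage_coupling has {len(self.stage_coupling)} entries "
                f"for {len(self.stages)} stages"
            )
        names = [f.name for f in self.features]
        if len(set(names)) != len(names):
            raise ValueError("duplicate feature names")
        for fi, fj, _ in self.interaction_pairs:
            if fi not in names or fj not in names:
                raise ValueError(f"interaction pair ({fi}, {fj}) names unknown feature")
        for f in self.features:
            if f.noise_sd <= 0:
                raise ValueError(f"{f.name}: noise_sd must be > 0")

    def weight_profile(self, f: FeatureSpec) -> np.ndarray:
        """w_f over the flattened canonical bin order."""
        labels = self.scheme.labels()
        k = len(labels)
        w = np.zeros(k)
        if f.profile == "none":
            return w
        if f.profile == "flat":
            return np.full(k, f.amplitude)
        if f.profile in ("tss_bump", "tts_bump"):
            c = labels.index(f.center)
            block = c // self.scheme.bins_per_anchor
            idx = np.arange(k)
            in_block = (idx // self.scheme.bins_per_anchor) == block
            w[in_block] = f.amplitude * np.exp(
                -((idx[in_block] - c) ** 2) / (2 * f.bump_sd_bins**2)
            )
            return w
        if f.profile == "decay":
            start = labels.index("TSS:d1")
            idx = np.arange(start, self.scheme.bins_per_anchor)
            w[idx] = f.amplitude * np.exp(-(idx - start) / f.decay_bins)
            # the transcribed body continues into the TTS-upstream block
            tts_u = np.arange(self.scheme.bins_per_anchor, self.scheme.bins_per_anchor + self.scheme.n_per_side)
            w[tts_u] = f.amplitude * 0.3
            return w
        raise ValueError(f"unknown profile {f.profile!r}")

    def coupled_window(self, f: FeatureSpec) -> list[int]:
        """Flattened bin indices where |w_f| is at least half its maximum."""
        w = self.weight_profile(f)
        if w.max() <= 0:
            return []
        return [int(i) for i in np.nonzero(w >= 0.5 * w.max())[0]]


@dataclass
class SyntheticDataset:
    """In-memory synthetic study plus optional on-disk serialisation."""

    spec: GeneratorSpec
    annotations: list[TranscriptAnnotation]
    operons: dict[str, list[str]]
    mirna_loci: list[TranscriptAnnotation]
    expression: ExpressionTable
    tensor: BinTensor
    mirna_signals: pd.DataFrame  # loci x features mean signal
    truth: dict
    tracks: list[SignalTrack] | None = None

    def write(self, outdir: str | Path) -> None:
        """Serialise as GFF3 + bedGraph tracks + TSV tables + truth JSON."""
        outdir = Path(outdir)
        (outdir / "tracks").mkdir(parents=True, exist_ok=True)
        if self.tracks is None:
            raise ValueError("dataset was generated without tracks; use generate(..., make_tracks=True)")
        with open(outdir / "annotation.gff3", "w") as fh:
            fh.write("##gff-version 3\n")
            for t in self.annotations:
                fh.write(
                    f"{t.chrom}\tchromexpress\tmRNA\t{t.start + 1}\t{t.end}\t.\t"
                    f"{t.strand}\t.\tID={t.transcript_id};Parent={t.gene_id}\n"
                )
        if self.mirna_loci:
            with open(outdir / "mirna.gff3", "w") as fh:
                fh.write("##gff-version 3\n")
                for t in self.mirna_loci:
                    fh.write(
                        f"{t.chrom}\tchromexpress\tmiRNA_primary_transcript\t"
                        f"{t.start + 1}\t{t.end}\t.\t{t.strand}\t.\tID={t.transcript_id}\n"
                    )
        with open(outdir / "tracks.tsv", "w") as fh:
            for tr in self.tracks:
                rel = f"tracks/{tr.feature_name}.bedgraph"
                fh.write(f"{tr.feature_name}\t{tr.stage}\t{tr.assay}\t{rel}\n")
                with open(outdir / rel, "w") as bg:
                    for chrom, start, end, *val in tr.intervals:
                        if tr.assay == "probe":
                            bg.write(f"{chrom}\t{start}\t{end}\t{repr(float(val[0]))}\n")
                        else:
                            bg.write(f"{chrom}\t{start}\t{end}\n")
        self.expression.to_tsv(outdir / "expression.tsv")
        if self.operons:
            with open(outdir / "operons.tsv", "w") as fh:
                for op, genes in self.operons.items():
                    fh.write(f"{op}\t{','.join(genes)}\n")
        with open(outdir / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=1, sort_keys=True)


def _activities(
    rng: np.random.Generator,
    f: FeatureSpec,
    n: int,
    z: np.ndarray,
    redundancy: float,
) -> np.ndarray:
    """Standardised latent activity for one feature.

    Coupled features load on the shared factor ``z`` with weight
    ``redundancy`` and sign ``f.sign``; decoy features are independent.
    Bimodal features threshold their latent into a two-component mixture.
    """
    r = redundancy if f.coupled else 0.0
    base = f.sign * math.sqrt(r) * z + math.sqrt(1 - r) * rng.normal(size=n)
    if f.bimodal:
        comp = (base > 0).astype(float)
        raw = comp * f.bimodal_sep + rng.normal(size=n)
        mean = f.bimodal_sep / 2.0
        sd = math.sqrt(1.0 + f.bimodal_sep**2 / 4.0)
        return (raw - mean) / sd
    return base


def generate(
    spec: GeneratorSpec,
    outdir: str | Path | None = None,
    make_tracks: bool | None = None,
) -> SyntheticDataset:
    """Generate a complete synthetic study from ``spec``.

    ``make_tracks`` controls whether genomic bedGraph-style tracks are
    materialised (needed for serialisation and for exercising the genomic
    aggregation path); by default they are built only for small studies
    (n <= 400) or when ``outdir`` is given.  The bin tensor is always
    available: from aggregation when tracks exist, otherwise directly from
    the generative model (identical by construction, since every probe
    covers exactly one bin).
    """
    rng = np.random.default_rng(spec.seed)
    if make_tracks is None:
        make_tracks = outdir is not None or spec.n_transcripts <= 400
    scheme = spec.scheme
    labels = scheme.labels()
    k = scheme.total_bins

    # --- genomic layout: well-separated transcripts on one contig
    gap = 2 * scheme.flank_bp + 200
    annotations: list[TranscriptAnnotation] = []
    cursor = 3 * scheme.flank_bp
    lengths = rng.integers(*spec.transcript_length_range, size=spec.n_transcripts)
    strands = rng.choice(["+", "-"], size=spec.n_transcripts)
    for i in range(spec.n_transcripts):
        annotations.append(
            TranscriptAnnotation(
                f"t{i:05d}", f"g{i:05d}", spec.chrom, str(strands[i]),
                int(cursor), int(cursor + lengths[i]),
            )
        )
        cursor += int(lengths[i]) + gap

    # --- operons: consecutive extra genes sharing the first gene's promoter
    operons: dict[str, list[str]] = {}
    operon_annos: list[TranscriptAnnotation] = []
    operon_role: dict[str, str] = {}  # transcript -> 'first'/'internal'
    for oi in range(spec.n_operons):
        size = int(rng.choice(spec.operon_sizes))
        genes = []
        for pos in range(size):
            tid = f"op{oi:03d}_{pos}"
            length = int(rng.integers(1000, 2500))
            operon_annos.append(
                TranscriptAnnotation(tid, tid, spec.chrom, "+", cursor, cursor + length, role="operon_member")
            )
            operon_role[tid] = "first" if pos == 0 else "internal"
            genes.append(tid)
            cursor += length + 200  # short intercistronic gaps
        operons[f"operon{oi:03d}"] = genes
        cursor += gap
    all_annos = annotations + operon_annos
    n_all = len(all_annos)

    # --- pre-miRNA loci in the intergenic space
    mirna_loci: list[TranscriptAnnotation] = []
    for mi in range(spec.n_mirnas):
        cursor += gap
        length = int(rng.integers(80, 120))
        mirna_loci.append(
            TranscriptAnnotation(
                f"mir{mi:03d}", f"mir{mi:03d}", spec.chrom,
                str(rng.choice(["+", "-"])), cursor, cursor + length, role="pre_mirna",
            )
        )
        cursor += length

    # --- latent activities and expression
    m = len(spec.features)
    z = rng.normal(size=n_all)  # shared mark factor (redundancy)
    A = np.column_stack(
        [_activities(rng, f, n_all, z, spec.feature_redundancy) for f in spec.features]
    )
    betas = np.array([f.sign * f.beta if f.coupled else 0.0 for f in spec.features])
    name_to_j = {f.name: j for j, f in enumerate(spec.features)}
    g = A @ betas
    for fi, fj, coeff in spec.interaction_pairs:
        g = g + coeff * A[:, name_to_j[fi]] * A[:, name_to_j[fj]]
    sigma_g = float(np.std(g)) or 1.0
    g_std = g / sigma_g

    e = np.empty((n_all, len(spec.stages)))
    for s, rho in enumerate(spec.stage_coupling):
        eta = rng.normal(size=n_all)
        eps = rng.normal(size=n_all)
        e[:, s] = (
            spec.expr_scale * (rho * g_std + math.sqrt(max(0.0, 1 - rho**2)) * eta)
            + spec.expr_noise_sd * eps
        )

    # operon internal genes: expression weakly tied to the first gene's
    # (shared promoter, heavy post-transcriptional divergence), chromatin
    # decoupled, and systematically lower: 2-fold for second genes, 3-fold
    # for last.  Variance-matched mixing keeps the log-scale marginal
    # distribution, so the mean RPKM ratios equal the fold drops.
    rho_op = 0.3
    sd_e = math.sqrt(spec.expr_scale**2 + spec.expr_noise_sd**2)
    tid_to_row = {t.transcript_id: i for i, t in enumerate(all_annos)}
    for op, genes in operons.items():
        first = tid_to_row[genes[0]]
        for pos, gid in enumerate(genes[1:], start=1):
            row = tid_to_row[gid]
            is_last = pos == len(genes) - 1
            drop = math.log2(3.0) if is_last else 1.0
            indep = rng.normal(scale=sd_e, size=len(spec.stages))
            e[row, :] = rho_op * e[first, :] + math.sqrt(1 - rho_op**2) * indep - drop
            A[row, :] = rng.normal(size=m)  # decouple chromatin from expression

    rpkm = np.maximum(np.exp2(spec.expr_mu + e) - 1.0, 0.0)

    # --- bin signal
    W = np.column_stack([spec.weight_profile(f) for f in spec.features])  # k x m
    noise_sd = np.array([f.noise_sd for f in spec.features])
    signal = np.empty((n_all, m, k))
    for j, f in enumerate(spec.features):
        raw = np.outer(A[:, j], W[:, j]) + rng.normal(scale=noise_sd[j], size=(n_all, k))
        if f.assay == "read":
            raw = rng.poisson(np.exp(0.5 + 0.8 * np.outer(A[:, j], W[:, j]))).astype(float)
        signal[:, j, :] = raw

    # --- miRNA signal: same law, single ~100 nt window at the locus peak
    n_mir = len(mirna_loci)
    mirna_signals = pd.DataFrame(
        index=[t.transcript_id for t in mirna_loci],
        columns=[f.name for f in spec.features],
        dtype=float,
    )
    e_mir = np.zeros((n_mir, len(spec.stages)))
    if n_mir:
        z_mir = rng.normal(size=n_mir)
        A_mir = np.column_stack(
            [_activities(rng, f, n_mir, z_mir, spec.feature_redundancy) for f in spec.features]
        )
        g_mir = A_mir @ betas
        for fi, fj, coeff in spec.interaction_pairs:
            g_mir = g_mir + coeff * A_mir[:, name_to_j[fi]] * A_mir[:, name_to_j[fj]]
        g_mir_std = g_mir / sigma_g  # same law as coding genes
        for s, rho in enumerate(spec.stage_coupling):
            eta = rng.normal(size=n_mir)
            eps = rng.normal(size=n_mir)
            e_mir[:, s] = (
                spec.expr_scale * (rho * g_mir_std + math.sqrt(max(0.0, 1 - rho**2)) * eta)
                + spec.expr_noise_sd * eps
            )
        peak = {f.name: float(spec.weight_profile(f).max()) for f in spec.features}
        for j, f in enumerate(spec.features):
            vals = peak[f.name] * A_mir[:, j] + rng.normal(scale=f.noise_sd, size=n_mir)
            if f.assay == "read":
                vals = rng.poisson(np.exp(0.5 + 0.8 * peak[f.name] * A_mir[:, j])).astype(float)
            mirna_signals[f.name] = vals

    # --- expression table over coding + operon + miRNA transcripts
    ids = [t.transcript_id for t in all_annos] + [t.transcript_id for t in mirna_loci]
    rpkm_mir = np.maximum(np.exp2(spec.expr_mu + e_mir) - 1.0, 0.0) if n_mir else np.zeros((0, len(spec.stages)))
    expr = ExpressionTable(
        pd.DataFrame(
            np.vstack([rpkm, rpkm_mir]) if n_mir else rpkm,
            index=ids, columns=list(spec.stages),
        )
    )

    # --- tracks and tensor
    tracks = None
    if make_tracks:
        tracks = _emit_tracks(spec, all_annos, mirna_loci, signal, mirna_signals)
        tensor = build_tensor(all_annos, tracks, scheme)
    else:
        tensor = BinTensor(
            [t.transcript_id for t in all_annos],
            [f.name for f in spec.features],
            signal,
            np.zeros_like(signal, dtype=bool),
            labels,
            scheme,
        )

    truth = {
        "seed": spec.seed,
        "feature_signs": {f.name: f.sign for f in spec.features},
        "feature_betas": {f.name: f.beta if f.coupled else 0.0 for f in spec.features},
        "coupled_features": [f.name for f in spec.features if f.coupled],
        "coupled_windows": {f.name: spec.coupled_window(f) for f in spec.features},
        "bump_centers": {
            f.name: labels.index(f.center)
            for f in spec.features
            if f.profile in ("tss_bump", "tts_bump")
        },
        "sigma_g": sigma_g,
        "feature_redundancy": spec.feature_redundancy,
        "stage_coupling": list(spec.stage_coupling),
        "g": [float(v) for v in g_std],
        "latent_expression": {s: [float(v) for v in e[:, i]] for i, s in enumerate(spec.stages)},
        "activities": {f.name: [float(v) for v in A[:, j]] for j, f in enumerate(spec.features)},
        "interaction_pairs": [list(p) for p in spec.interaction_pairs],
        "operon_role": operon_role,
    }

    ds = SyntheticDataset(
        spec=spec,
        annotations=all_annos,
        operons=operons,
        mirna_loci=mirna_loci,
        expression=expr,
        tensor=tensor,
        mirna_signals=mirna_signals,
        truth=truth,
        tracks=tracks,
    )
    if outdir is not None:
        ds.write(outdir)
    return ds


def _emit_tracks(spec, annotations, mirna_loci, signal, mirna_signals) -> list[SignalTrack]:
    """Materialise per-feature genomic tracks from the bin-level signal.

    Each probe covers exactly one bin of one transcript; when two
    transcripts' windows overlap genomically (operons), the first writer
    wins and the later bin goes unprobed.  Read features emit one
    bin-aligned read per Poisson count.
    """
    import bisect

    scheme = spec.scheme
    tracks = []
    for j, f in enumerate(spec.features):
        intervals: list[tuple] = []
        occ_starts: list[int] = []  # sorted, non-overlapping once inserted
        occ_ends: list[int] = []

        def free(lo: int, hi: int) -> bool:
            i = bisect.bisect_right(occ_starts, lo)
            if i > 0 and occ_ends[i - 1] > lo:
                return False
            if i < len(occ_starts) and occ_starts[i] < hi:
                return False
            return True

        def occupy(lo: int, hi: int) -> None:
            i = bisect.bisect_right(occ_starts, lo)
            occ_starts.insert(i, lo)
            occ_ends.insert(i, hi)

        for i, t in enumerate(annotations):
            for b, bin_ in enumerate(make_bins(t, scheme)):
                if bin_.start < 0 or not free(bin_.start, bin_.end):
                    continue
                occupy(bin_.start, bin_.end)
                if f.assay == "probe":
                    intervals.append((bin_.chrom, bin_.start, bin_.end, signal[i, j, b]))
                else:
                    for _ in range(int(signal[i, j, b])):
                        intervals.append((bin_.chrom, bin_.start, bin_.end))
        for t in mirna_loci:
            if not free(t.start, t.end):
                continue
            occupy(t.start, t.end)
            v = mirna_signals.loc[t.transcript_id, f.name]
            if f.assay == "probe":
                intervals.append((t.chrom, t.start, t.end, float(v)))
            else:
                for _ in range(int(v)):
                    intervals.append((t.chrom, t.start, t.end))
        tracks.append(SignalTrack(f.name, spec.stages[0], f.assay, intervals))
    return tracks


def generate_tensor(spec: GeneratorSpec) -> SyntheticDataset:
    """Fast path: the same study without materialising genomic tracks."""
    return generate(spec, make_tracks=False)


def worked_example_small() -> SyntheticDataset:
    """A 10-transcript, 3-feature micro-study with hand-checkable bin values.

    Uses a 200 bp flank and 100 bp bins (4 bins per transcript per anchor,
    8 total).  Probe values follow the closed form
    ``value = 10 * (i + 1) + b`` for transcript i at flattened bin b of
    ``mark_act`` and ``90 - 5 * i + b`` for ``mark_rep``; the read feature
    ``polii`` places ``i mod 4`` bin-aligned reads in the first transcribed
    bin of transcript i, plus one read overlapping transcript 0's TSS:d1 bin
    by exactly 25 of its 100 bp (contributing 0.25 there and 0.75 to
    TSS:u1).  Deterministic: no random numbers are drawn.
    """
    scheme = BinScheme(flank_bp=200, bin_width_bp=100)
    labels = scheme.labels()
    k = scheme.total_bins
    annotations = []
    for i in range(10):
        start = 1000 + i * 2000
        strand = "+" if i % 2 == 0 else "-"
        annotations.append(
            TranscriptAnnotation(f"t{i:02d}", f"g{i:02d}", "chrI", strand, start, start + 600)
        )
    rpkm_eemb = [5.0, 3.0, 8.0, 1.0, 9.0, 2.0, 7.0, 0.0, 6.0, 4.0]
    expr = ExpressionTable(
        pd.DataFrame({"EEMB": rpkm_eemb}, index=[t.transcript_id for t in annotations])
    )

    act_intervals, rep_intervals, read_intervals = [], [], []
    for i, t in enumerate(annotations):
        for b, bin_ in enumerate(make_bins(t, scheme)):
            act_intervals.append((bin_.chrom, bin_.start, bin_.end, float(10 * (i + 1) + b)))
            rep_intervals.append((bin_.chrom, bin_.start, bin_.end, float(90 - 5 * i + b)))
            if bin_.label == "TSS:d1":
                for _ in range(i % 4):
                    read_intervals.append((bin_.chrom, bin_.start, bin_.end))
    # one designed read overlapping transcript 0's TSS:d1 = [1000, 1100) by 25 bp
    read_intervals.append(("chrI", 925, 1025))

    tracks = [
        SignalTrack("mark_act", "EEMB", "probe", act_intervals),
        SignalTrack("mark_rep", "EEMB", "probe", rep_intervals),
        SignalTrack("polii", "EEMB", "read", read_intervals),
    ]
    tensor = build_tensor(annotations, tracks, scheme)

    spec = GeneratorSpec(
        seed=0, n_transcripts=10,
        features=[
            FeatureSpec("mark_act", profile="flat"),
            FeatureSpec("mark_rep", sign=-1, profile="flat"),
            FeatureSpec("polii", profile="flat", assay="read"),
        ],
        stages=("EEMB",), stage_coupling=(1.0,), scheme=scheme,
    )
    # Spearman of mark_act at TSS:u1 vs RPKM: signal is monotone in i, so the
    # value equals the rank-formula correlation of (0..9) with the RPKM ranks.
    d = np.arange(10) - np.argsort(np.argsort(rpkm_eemb))
    rho_u1 = 1 - 6 * float(np.sum(d.astype(float) ** 2)) / (10 * (100 - 1))
    truth = {
        "rpkm_EEMB": rpkm_eemb,
        "spearman_mark_act_TSSu1": rho_u1,
        "designed_read_overlap": {"transcript": "t00", "bin": "TSS:d1", "value": 0.25},
    }
    return SyntheticDataset(
        spec=spec,
        annotations=annotations,
        operons={},
        mirna_loci=[],
        expression=expr,
        tensor=tensor,
        mirna_signals=pd.DataFrame(),
        truth=truth,
        tracks=tracks,
    )
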