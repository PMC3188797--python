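"""Run configuration, feature-subset definitions, and output manifests."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

__version__ = "1.0.0"

# Named predictor subsets; ALL is resolved against the tensor at run time.
DEFAULT_SUBSETS: dict[str, list[str]] = {
    "H3": ["H3"],
    "HIS": [
        "H3K4me2", "H3K4me3", "H3K9me2", "H3K9me3", "H3K27me3",
        "H3K36me2", "H3K36me3", "H3K79me1", "H3K79me2", "H3K79me3",
    ],
    "XIF": ["MES4", "MRG1", "SDC2", "DPY27"],
    "POLII": ["POLII"],
    "K4": ["H3K4me2", "H3K4me3"],
    "K9": ["H3K9me2", "H3K9me3"],
    "K36": ["H3K36me2", "H3K36me3"],
    "K79": ["H3K79me1", "H3K79me2", "H3K79me3"],
}


@dataclass
class RunConfig:
    """Every tunable of the toolkit, with defaults, JSON round-trip and
    schema validation.  CLI flags override config-file values."""

    flank_bp: int = 4000
    bin_width_bp: int = 100
    stage: str = "EEMB"
    svm_C: float = 1.0
    svm_gamma: float | None = None  # None -> 1 / n_predictors
    svr_epsilon: float = 0.1
    n_repeats: int = 100
    cv_split: float = 0.5
    alpha: float = 0.001
    mi_k_bins: int = 3
    min_pairs: int = 10
    coverage_quantile: float = 0.9
    fold_change: float = 4.0
    pseudocount: float = 1.0
    seed: int = 0
    subsets: dict = field(default_factory=lambda: dict(DEFAULT_SUBSETS))

    def validate(self) -> None:
        checks = {
            "flank_bp": self.flank_bp > 0,
            "bin_width_bp": self.bin_width_bp > 0 and self.flank_bp % self.bin_width_bp == 0,
            "svm_C": self.svm_C > 0,
            "n_repeats": self.n_repeats >= 1,
            "cv_split": 0 < self.cv_split < 1,
            "alpha": 0 < self.alpha < 1,
            "mi_k_bins": self.mi_k_bins >= 2,
            "coverage_quantile": 0 < self.coverage_quantile < 1,
            "fold_change": self.fold_change >= 1,
            "seed": isinstance(self.seed, int),
        }
        bad = [name for name, ok in checks.items() if not ok]
        if bad:
            raise ValueError(f"invalid configuration field(s): {', '.join(bad)}")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = json.load(fh)
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown configuration field(s): {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        return asdict(self)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(outdir: str | Path, config: RunConfig, inputs: list, subcommand: str) -> None:
    """Record provenance next to every output: config, seed, input hashes."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "tool": "chromexpress",
        "version": __version__,
        "subcommand": subcommand,
        "config": config.to_dict(),
        "inputs": {
            str(p): _sha256(Path(p)) for p in inputs if Path(p).is_file()
        },
    }
    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
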