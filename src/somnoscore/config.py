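"""Pipeline configuration: a validated YAML-backed parameter set.

The defaults are the operating point of the published pipeline: 0.5–50 Hz
band-pass, knowledge-based features over the standard band set, a linear
RVM one-against-all classifier (RBF gamma 0.5 when the RBF kernel is
chosen), k = 13 for the k-NN baseline and C = 50 for the SVM comparison.
Unknown keys in a config file are rejected rather than ignored.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .classifiers import KernelSpec
from .features import DEFAULT_BANDS, BandDefinition
from .preprocess import FilterSpec


@dataclass
class PipelineConfig:
    filter: FilterSpec = field(default_factory=FilterSpec)
    bands: dict[str, BandDefinition] = field(
        default_factory=lambda: dict(DEFAULT_BANDS)
    )
    feature_mode: str = "knowledge"  # or "conventional"
    classifier: str = "rvm"  # rvm | svm | lda | knn
    kernel: KernelSpec = field(default_factory=KernelSpec)
    knn_k: int = 13
    svm_c: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.feature_mode not in ("knowledge", "conventional"):
            raise ValueError(f"unknown feature_mode {self.feature_mode!r}")
        if self.classifier not in ("rvm", "svm", "lda", "knn"):
            raise ValueError(f"unknown classifier {self.classifier!r}")

    def to_dict(self) -> dict:
        return {
            "filter": dataclasses.asdict(self.filter),
            "bands": {
                name: {"low_hz": b.low_hz, "high_hz": b.high_hz}
                for name, b in self.bands.items()
            },
            "feature_mode": self.feature_mode,
            "classifier": self.classifier,
            "kernel": dataclasses.asdict(self.kernel),
            "knn_k": self.knn_k,
            "svm_c": self.svm_c,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {
            "filter",
            "bands",
            "feature_mode",
            "classifier",
            "kernel",
            "knn_k",
            "svm_c",
            "seed",
        }
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        kwargs: dict = {}
        if "filter" in data:
            extra = set(data["filter"]) - {f.name for f in dataclasses.fields(FilterSpec)}
            if extra:
                raise ValueError(f"unknown filter key(s): {sorted(extra)}")
            kwargs["filter"] = FilterSpec(**data["filter"])
        if "bands" in data:
            kwargs["bands"] = {
                name: BandDefinition(name, **spec) for name, spec in data["bands"].items()
            }
        if "kernel" in data:
            extra = set(data["kernel"]) - {f.name for f in dataclasses.fields(KernelSpec)}
            if extra:
                raise ValueError(f"unknown kernel key(s): {sorted(extra)}")
            kwargs["kernel"] = KernelSpec(**data["kernel"])
        for key in ("feature_mode", "classifier", "knn_k", "svm_c", "seed"):
            if key in data:
                kwargs[key] = data[key]
        return cls(**kwargs)

    def save_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load_yaml(cls, path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def make_classifier(self):
        from .classifiers import SleepStageClassifier

        return SleepStageClassifier(
            kind=self.classifier, kernel=self.kernel, k=self.knn_k, C=self.svm_c
        )
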