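"""Pipeline configuration: one validated object, YAML-serializable."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from robustrad.core import ALL_MAP_NAMES
from robustrad.phantom import AcquisitionSpec, CohortSpec

#: default discretization bin width per map (maps live on very different
#: scales: TTP in seconds, VE a fraction, ...)
DEFAULT_BIN_WIDTHS: dict[str, float] = {
    "MRE": 10.0,      # %
    "TTP": 19.0,      # s (half the frame interval)
    "WIS": 0.2,       # %/s
    "WOS": 0.02,      # %/s
    "WOR": 0.05,      # dimensionless
    "WIO": 5.0,       # dimensionless ratio (capped)
    "KTRANS": 0.05,   # min^-1
    "VE": 0.05,       # fraction
    "VP": 0.02,       # fraction
    "D": 1e-4,        # mm^2/s
    "DSTAR": 0.02,    # mm^2/s
    "F": 0.05,        # fraction
}


@dataclass
class PipelineConfig:
    """Everything a full phantom-to-classification run needs."""

    out_dir: str = "robustrad_run"
    seed: int = 0
    acquisition: AcquisitionSpec = field(default_factory=AcquisitionSpec)
    cohort: CohortSpec = field(default_factory=CohortSpec)
    aif_model: str = "weinmann"
    alpha: float = 4.0                       # relative enhancement per mmol/L
    bin_widths: dict = field(default_factory=lambda: dict(DEFAULT_BIN_WIDTHS))
    icc_threshold: float = 0.9
    selectors: tuple = ("auc", "relieff", "lasso", "backward")
    classifiers: tuple = ("lda", "knn", "svm", "nnet")
    cv_k: int = 5
    cv_repetitions: int = 10                 # 100 reproduces the full protocol
    relieff_permutations: int = 500

    def validate(self) -> None:
        if not 0 < self.icc_threshold < 1:
            raise ValueError(f"icc_threshold {self.icc_threshold} outside (0, 1)")
        missing = [m for m in ALL_MAP_NAMES if m not in self.bin_widths]
        if missing:
            raise ValueError(f"bin_widths missing maps: {missing}")
        if any(w <= 0 for w in self.bin_widths.values()):
            raise ValueError("bin widths must be positive")
        if self.cv_k < 2 or self.cv_repetitions < 1:
            raise ValueError("cv_k >= 2 and cv_repetitions >= 1 required")
        unknown = set(self.selectors) - {"auc", "relieff", "lasso", "backward"}
        if unknown:
            raise ValueError(f"unknown selectors: {sorted(unknown)}")
        unknown = set(self.classifiers) - {"lda", "knn", "svm", "nnet"}
        if unknown:
            raise ValueError(f"unknown classifiers: {sorted(unknown)}")

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["acquisition"] = asdict(self.acquisition)
        d["cohort"] = asdict(self.cohort)
        Path(path).write_text(yaml.safe_dump(_listify(d), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        if "acquisition" in raw:
            acq = dict(raw["acquisition"])
            for key in ("dwi_b_values", "grid_shape", "voxel_spacing"):
                if key in acq:
                    acq[key] = tuple(acq[key])
            raw["acquisition"] = AcquisitionSpec(**acq)
        if "cohort" in raw:
            coh = dict(raw["cohort"])
            for key in ("radii_range_mm",):
                if key in coh:
                    coh[key] = tuple(coh[key])
            if "class_distributions" in coh:
                coh["class_distributions"] = {
                    c: {p: tuple(v) for p, v in d.items()}
                    for c, d in coh["class_distributions"].items()
                }
            raw["cohort"] = CohortSpec(**coh)
        for key in ("selectors", "classifiers"):
            if key in raw:
                raw[key] = tuple(raw[key])
        cfg = cls(**raw)
        cfg.validate()
        return cfg


def _listify(obj):
    """Tuples -> lists so YAML stays plain."""
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    if isinstance(obj, (tuple, list)):
        return [_listify(v) for v in obj]
    return obj
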