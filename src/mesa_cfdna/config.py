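"""Declarative run configuration with lossless YAML round-trip."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import yaml

from .classify import ModelConfig
from .errors import UsageError

DEFAULT_MODALITIES = ["methylation", "occupancy", "fuzziness", "wps"]


@dataclass
class RunConfig:
    """Everything one pipeline run needs; defaults are the protocol values
    (fragment filter 80–200 bp, lambda QC 1%, top 100 features, 10 inner
    folds, sensitivity read at 90% specificity)."""

    sample_sheet: str = ""
    meth_panel: str = ""
    nuc_panel: str = ""
    outdir: str = "mesa_run"
    # fragment filter and QC
    min_frag_len: int = 80
    max_frag_len: int = 200
    qc_max_lambda: float = 0.01
    qc_override: bool = False        # keep QC-indeterminate samples
    # feature extraction
    modalities: list[str] = field(default_factory=lambda: list(DEFAULT_MODALITIES))
    mode: str = "region"             # or "window" (1 kb sliding windows)
    window: int = 1000
    step: int = 10
    wps_window: int = 120
    wps_frag_range: list[int] | None = None  # e.g. [120, 180]: strict WPS filter
    min_summit_occ: float = 0.5
    smooth_window: int = 73
    min_fuzziness_support: int = 20  # mean frags/region below which fuzziness is dropped
    selection_report: bool = True
    # modelling
    model: ModelConfig = field(default_factory=ModelConfig)
    seed: int = 0

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        model_data = data.pop("model", {}) or {}
        known = {f.name for f in dataclasses.fields(cls)} - {"model"}
        unknown = set(data) - known
        if unknown:
            raise UsageError(f"unknown config key(s): {sorted(unknown)}")
        model_known = {f.name for f in dataclasses.fields(ModelConfig)}
        bad = set(model_data) - model_known
        if bad:
            raise UsageError(f"unknown model config key(s): {sorted(bad)}")
        return cls(model=ModelConfig(**model_data), **data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise UsageError("config file must contain a mapping")
        return cls.from_dict(data)

    def digest(self) -> str:
        """Stable hash of the full configuration."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
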