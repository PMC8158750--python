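"""Flat key-value pipeline configuration with lossless round-trip."""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, fields
from pathlib import Path


@dataclass
class PipelineConfig:
    """Resolved parameters of one end-to-end run."""

    # cohort
    n_subjects: int = 4
    sr_duration_s: float = 84.0
    vf_duration_s: float = 21.0
    ma_duration_s: float = 28.0
    ventilator: bool = True
    # preprocessing
    use_lms: bool = True
    lms_length: int = 64
    lms_alpha: float = 1.0
    lms_mu: float = 1e-8
    sg_window: int = 31
    sg_order: int = 3
    # transform
    f_lo: float = 1.0
    f_hi: float = 20.0
    hbl_min: int = 44
    hbl_max: int = 150
    quantization: int = 10
    # analysis / selection
    fdr_level: float = 0.05
    feature_mode: str = "paper"  # or "data_driven"
    cluster_cut: float = 1.0
    # classification
    model: str = "rf"  # or "lr"
    paradigm: str = "kfold10"  # or "loso"
    repeats: int = 10
    seed: int = 0

    def to_file(self, path: str | Path) -> Path:
        path = Path(path)
        lines = [f"{k}={v!r}" for k, v in sorted(asdict(self).items())]
        path.write_text("\n".join(lines) + "\n")
        return path

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        import ast

        raw: dict[str, object] = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            raw[key.strip()] = ast.literal_eval(value.strip())
        kwargs = {f.name: raw[f.name] for f in fields(cls) if f.name in raw}
        return cls(**kwargs)

    def digest(self) -> str:
        """Short content hash naming cached stage outputs."""
        payload = "\n".join(f"{k}={v!r}" for k, v in sorted(asdict(self).items()))
        return hashlib.sha256(payload.encode()).hexdigest()[:10]
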