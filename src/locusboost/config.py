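"""Flat key=value run configuration with CLI override precedence."""

from __future__ import annotations

from pathlib import Path

DEFAULTS: dict[str, str] = {
    # locus mapping
    "r2_min": "0.5",
    "flank_bp": "250000",
    "fallback_bp": "50000",
    # prior weighting
    "evidence_pts": "5",
    "proximity_bp": "50000",
    "likely_positive_min": "10",
    "adj_p_max": "0.05",
    "lod_min": "1.0",
    # training
    "mode": "gwa",
    "n_rounds": "6",
    "n_folds": "8",
    "n_main_trees": "60",
    "n_burnin_trees": "20",
    "n_leaves": "4",
    "locus_fraction": "0.7",
    "shrinkage": "0.1",
    "burnin_keep_fraction": "0.25",
    "epsilon": "0.001",
    "seed": "0",
}


def load_config(path: str | Path | None) -> dict[str, str]:
    """Defaults overlaid with a key=value file (unknown keys rejected)."""
    cfg = dict(DEFAULTS)
    if path is None:
        return cfg
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{i}: expected key=value")
        key, _, value = line.partition("=")
        key = key.strip()
        if key not in DEFAULTS:
            raise ValueError(f"{path}:{i}: unknown key {key!r}")
        cfg[key] = value.strip()
    return cfg


def show_config(cfg: dict[str, str]) -> str:
    return "\n".join(f"{k}={cfg[k]}" for k in sorted(cfg))
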