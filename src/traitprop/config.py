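"""Run configuration: every tunable of the pipeline, with validation.

Defaults mirror the method's published operating point: d=30 LSI components,
k=30 mutual neighbors, restart probability gamma=0.05, convergence tolerance
alpha=1e-5, seed threshold P<0.05 capped at 5% of cells, 50 background sets,
B=1000 permutations, 99th-percentile ceiling and top-1% scaling for the TRS,
and the pp>0.001 variant filter.
"""
from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path


@dataclass
class RunConfig:
    # inputs / outputs
    matrix: str | None = None
    peaks: str | None = None
    barcodes: str | None = None
    variants: str | None = None
    out_dir: str = "traitprop_out"
    # variant filter
    pp_threshold: float = 0.001
    # trait scoring
    n_background: int = 50
    bg_neighbors: int = 100
    # embedding / graph
    d: int = 30
    k: int = 30
    tf_mode: str = "frequency"
    bridge_components: bool = False
    # propagation
    gamma: float = 0.05
    alpha: float = 1e-5
    p_threshold: float = 0.05
    max_seed_fraction: float = 0.05
    max_iter: int = 10000
    percentile: float = 0.99
    top_fraction_for_scaling: float = 0.01
    scaling_mode: str = "mean_z"
    # permutation test
    permutations: bool = False
    B: int = 1000
    state_alpha: float = 0.05
    # one master seed fans out to per-stage streams
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


def validate_config(config: RunConfig, n_cells: int | None = None,
                    n_peaks: int | None = None, require_inputs: bool = True) -> RunConfig:
    """Check ranges and input paths before any heavy computation.

    Every violation is reported with its offending key.  Dimension-dependent
    checks (k vs N, d vs matrix size) run when sizes are supplied.
    """
    problems: list[str] = []
    if require_inputs:
        for key in ("matrix", "peaks", "barcodes", "variants"):
            value = getattr(config, key)
            if value is None:
                problems.append(f"{key}: input path missing")
            elif not Path(value).exists():
                problems.append(f"{key}: file not found ({value})")
    if not (0.0 < config.gamma <= 1.0):
        problems.append("gamma: restart probability must be in (0, 1]")
    if config.alpha <= 0:
        problems.append("alpha: convergence tolerance must be > 0")
    for key in ("p_threshold", "max_seed_fraction", "percentile",
                "top_fraction_for_scaling", "state_alpha"):
        value = getattr(config, key)
        if not (0.0 < value <= 1.0):
            problems.append(f"{key}: must be in (0, 1]")
    if not (0.0 <= config.pp_threshold < 1.0):
        problems.append("pp_threshold: must be in [0, 1)")
    for key in ("d", "k", "n_background", "bg_neighbors", "B", "max_iter"):
        if getattr(config, key) < 1:
            problems.append(f"{key}: must be >= 1")
    if config.d < 2:
        problems.append("d: at least 2 LSI components are required")
    if config.tf_mode not in ("frequency", "binary"):
        problems.append("tf_mode: must be 'frequency' or 'binary'")
    if config.scaling_mode not in ("mean_z", "mean_np"):
        problems.append("scaling_mode: must be 'mean_z' or 'mean_np'")
    if n_cells is not None and config.k >= n_cells:
        problems.append(f"k: must be smaller than the number of cells ({n_cells})")
    if n_cells is not None and n_peaks is not None:
        if config.d > min(n_cells, n_peaks) - 1:
            problems.append(f"d: must be <= min(peaks, cells) - 1 = {min(n_cells, n_peaks) - 1}")
    if problems:
        raise ValueError("invalid configuration:\n  " + "\n  ".join(problems))
    return config
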