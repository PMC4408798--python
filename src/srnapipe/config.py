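"""Pipeline configuration: embedded defaults, YAML overlay, validation."""

from __future__ import annotations

import copy
from pathlib import Path
from typing import Any, Dict, Optional

import yaml

__all__ = ["DEFAULTS", "load_config", "dump_defaults"]

DEFAULTS: Dict[str, Any] = {
    "seed": 1,
    "outdir": "srnapipe_out",
    "paths": {
        "genome": None,  # None -> use the simulate stage's outputs
        "reads": None,
        "repeats": None,
        "genome_b": None,
        "reads_b": None,
        "ncrna_manifest": None,  # YAML: {label: fasta path}
        "pwm_files": [],  # plain-matrix or MEME-minimal files; empty -> builtin
    },
    "simulate": {
        "n_chrom": 3,
        "chrom_len": 300000,
        "n_clusters": 4,
        "cluster_len": 10000,
        "cluster_read_depth": 500,
        "u1_fraction": 0.85,
        "pingpong_fraction": 0.30,
        "hairpin_stem": 60,
        "hairpin_loop": 9,
        "duplex_read_len": 21,
        "n_duplex_pairs": 150,
        "motif_enrichment_fold": 3.0,
        "motif_sites_background": 60,
        "bidir_fraction": 0.3,
        "with_homolog": True,
    },
    "mapping": {"max_mm": 3, "mode": "nonidentical"},
    "annotate": {"fractions": [[18, 25], [26, 34]]},
    "clusters": {
        "window": 5000,
        "step": 1000,
        "density_factor": 10.0,
        "min_nonidentical": 25,
        "min_size": 1000,
        "biased_fraction": 0.75,
        "length_min": 24,
        "length_max": 34,
        "length_fraction": 0.75,
        "mono_fraction": 0.9,
        "bidir_fraction": 0.75,
    },
    "motifs": {"threshold": 0.8},
    "conservation": {
        "k": 12,
        "min_anchor": 30,
        "min_identity": 0.6,
        "min_total": 200,
        "match": 5.0,
        "mismatch": -4.0,
        "gap_open": 25.0,
        "gap_extend": 5.0,
    },
    "structure": {
        "window": 20,
        "max_fold_len": 10000,
        "n_bootstrap": 100,
        "max_mismatches": 3,
    },
}


def _merge(base: Dict[str, Any], overlay: Dict[str, Any]) -> Dict[str, Any]:
    out = copy.deepcopy(base)
    for key, val in overlay.items():
        if key in out and isinstance(out[key], dict) and isinstance(val, dict):
            out[key] = _merge(out[key], val)
        else:
            out[key] = val
    return out


def load_config(path: Optional[str | Path] = None) -> Dict[str, Any]:
    """Defaults overlaid with a YAML config file (validated shallowly)."""
    cfg = copy.deepcopy(DEFAULTS)
    if path is not None:
        with open(path) as fh:
            overlay = yaml.safe_load(fh) or {}
        unknown = set(overlay) - set(DEFAULTS)
        if unknown:
            raise ValueError(f"unknown config sections: {sorted(unknown)}")
        cfg = _merge(cfg, overlay)
    if not isinstance(cfg["seed"], int):
        raise ValueError("seed must be an integer")
    for key, p in cfg["paths"].items():
        if key == "pwm_files":
            for f in p or []:
                if not Path(f).exists():
                    raise FileNotFoundError(f"configured PWM file missing: {f}")
        elif p is not None and not Path(p).exists():
            raise FileNotFoundError(f"configured path {key} missing: {p}")
    return cfg


def dump_defaults() -> str:
    return yaml.safe_dump(DEFAULTS, sort_keys=False)
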