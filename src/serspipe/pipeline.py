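"""End-to-end orchestration over one or more replicates.

Per replicate: background removal -> signal detection -> signal merging, each
stage writing its table; then every replicate pair with signatures on both
sides is matched with the shift-tolerant metric.  A JSON report collects the
signature times per replicate (1-based) and the match table.  The analysis is
fully deterministic: all randomness lives in the synthetic-data generator.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import background, detection, matching, merging
from .exceptions import ParameterError, SersPipeError
from .io import read_spectra, write_spectra

logger = logging.getLogger(__name__)

#: published parameterizations: short-lived analytes (50/50) vs long-lasting
#: signals, which need a larger time window (150)
PRESETS: Dict[str, Dict[str, int]] = {
    "vitamin": {"window_time": 50, "window_freq": 50},
    "tumor": {"window_time": 150, "window_freq": 50},
}


@dataclass
class ReplicateInput:
    name: str
    spectra: str
    dialect: str = "tsv"
    has_header: bool = True


@dataclass
class PipelineConfig:
    """All stage parameters plus input/output plumbing."""

    replicates: List[ReplicateInput] = field(default_factory=list)
    output_dir: str = "serspipe_out"
    window_time: int = 50
    window_freq: int = 50
    percentile: float = 40.0
    alpha: float = 3.0
    beta: float = 0.05
    gamma: int = 3
    absolute_alpha: bool = False
    phi: float = 0.9
    max_shift: int = 10
    min_similarity: float = 0.5
    preset: Optional[str] = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.preset is not None:
            try:
                overrides = PRESETS[self.preset]
            except KeyError:
                raise ParameterError(
                    f"unknown preset {self.preset!r}; available: {sorted(PRESETS)}"
                ) from None
            for key, value in overrides.items():
                setattr(self, key, value)


def load_pipeline_config(path) -> PipelineConfig:
    """Read a pipeline configuration from YAML (keys mirror the CLI flags)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    reps = [
        ReplicateInput(**r) if isinstance(r, dict) else ReplicateInput(name=f"rep{i + 1}", spectra=r)
        for i, r in enumerate(raw.pop("replicates", []))
    ]
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ParameterError(f"unknown pipeline config keys: {sorted(unknown)}")
    return PipelineConfig(replicates=reps, **raw)


def _write_table(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full workflow and return (and write) the run report."""
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    if not cfg.replicates:
        raise ParameterError("pipeline config lists no replicates")
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "parameters": {
            k: v
            for k, v in dataclasses.asdict(cfg).items()
            if k not in ("replicates", "output_dir", "log_level")
        },
        "replicates": [],
        "matches": [],
    }
    signatures_by_rep: Dict[str, List[merging.SignatureSignal]] = {}

    for rep in cfg.replicates:
        logger.info(
            "replicate %s: windows %d/%d, percentile %g, alpha %g, beta %g, gamma %d, phi %g",
            rep.name, cfg.window_time, cfg.window_freq, cfg.percentile,
            cfg.alpha, cfg.beta, cfg.gamma, cfg.phi,
        )
        try:
            m = read_spectra(rep.spectra, dialect=rep.dialect, has_header=rep.has_header)
            cs = background.remove_background(
                m, cfg.window_time, cfg.window_freq, cfg.percentile
            )
            write_spectra(cs, outdir / f"{rep.name}_corrected.tsv")
            det = detection.detect_signals(
                cs, cfg.alpha, cfg.beta, cfg.gamma, cfg.absolute_alpha
            )
            _write_table(
                detection.detections_to_table(det), outdir / f"{rep.name}_detections.tsv"
            )
            sigs = merging.merge_signals(cs, det, cfg.phi)
            write_signatures(sigs, outdir / f"{rep.name}_signatures.tsv", cs.wavenumber)
        except SersPipeError as exc:
            raise SersPipeError(f"replicate {rep.name!r}: {exc}") from exc
        signatures_by_rep[rep.name] = sigs
        report["replicates"].append(
            {
                "name": rep.name,
                "n_detected_times": int(det.detected_times.size),
                "detected_times": (det.detected_times + 1).tolist(),
                "signature_times": [s.time_index + 1 for s in sigs],
                "n_signatures": len(sigs),
            }
        )
        if not sigs:
            logger.info("replicate %s: zero signatures; it will be skipped in matching", rep.name)

    names = [rep.name for rep in cfg.replicates]
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = signatures_by_rep[names[i]], signatures_by_rep[names[j]]
            if not a or not b:
                continue
            pair_matches = matching.match_signatures(
                a, b, max_shift=cfg.max_shift, min_similarity=cfg.min_similarity
            )
            table = matching.matches_to_table(pair_matches, a, b)
            _write_table(table, outdir / f"matches_{names[i]}_{names[j]}.tsv")
            report["matches"].append(
                {
                    "pair": [names[i], names[j]],
                    "matches": table.to_dict(orient="records"),
                }
            )

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report


def write_signatures(
    signatures: Sequence[merging.SignatureSignal], path, wavenumber=None
) -> Path:
    """Write the signature metadata table plus a ``*_spectra.tsv`` sidecar
    holding one corrected spectrum per signature (signature_index first
    column)."""
    path = Path(path)
    _write_table(merging.signatures_to_table(signatures), path)
    side = path.with_name(path.stem + "_spectra.tsv")
    if signatures:
        w = signatures[0].spectrum.size
        axis = wavenumber if wavenumber is not None else np.arange(1, w + 1)
        header = "signature_index\t" + "\t".join(format(float(v), ".17g") for v in axis)
        body = [
            str(k + 1) + "\t" + "\t".join(format(float(v), ".17g") for v in s.spectrum)
            for k, s in enumerate(signatures)
        ]
        side.write_text(header + "\n" + "\n".join(body) + "\n")
    else:
        side.write_text("signature_index\n")
    return path


def read_signatures(path) -> List[merging.SignatureSignal]:
    """Read back a signature table and its spectra sidecar."""
    path = Path(path)
    meta = pd.read_csv(path, sep="\t")
    side = path.with_name(path.stem + "_spectra.tsv")
    spectra = pd.read_csv(side, sep="\t", float_precision="round_trip")
    out: List[merging.SignatureSignal] = []
    for _, row in meta.iterrows():
        k = int(row["signature_index"])
        spec_row = spectra.loc[spectra["signature_index"] == k].iloc[0]
        spectrum = spec_row.drop("signature_index").to_numpy(dtype=float)
        out.append(
            merging.SignatureSignal(
                time_index=int(row["time_index"]) - 1,
                spectrum=spectrum,
                support=merging.parse_support(row["support"]),
                strength=float(row["strength"]),
            )
        )
    return out
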