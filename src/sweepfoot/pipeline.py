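"""End-to-end sweep-detection pipeline: scan -> peaks -> null -> calls.

A single declarative configuration drives the chain: sliding-window D/H/E
along an aligned locus, peak identification, a coalescent null matched to
the window length, empirical probabilities P(Sim <= Obs) for the three
peaks, and the significance calls.  The report is deterministic for a
given config + inputs + seed: provenance records the package version and
SHA-256 digests of the inputs, never a timestamp.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass

import yaml

from . import __version__
from .coalescent import NullModel, build_null, call_significance, empirical_p
from .errors import ConfigError, SweepfootError
from .io import fasta_to_window, write_bed
from .popgen import find_peaks, sliding_scan

logger = logging.getLogger("sweepfoot")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    """Resolved parameters of one pipeline run (unknown keys rejected)."""

    fasta: str
    ancestral_id: str
    out_dir: str
    window: int = 2000
    step: int = 100
    n_reps: int = 10000
    theta_site: float = 7.6e-3
    rho_site: float = 2.5e-1
    alpha: float = 0.05
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            if str(path).endswith((".yml", ".yaml")):
                d = yaml.safe_load(fh)
            else:
                d = json.load(fh)
        return cls.from_dict(d)

    def resolved(self) -> dict:
        return dataclasses.asdict(self)


def _digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run scan -> peaks -> null -> empirical P -> significance calls.

    Writes windows.bed, peaks.tsv and report.json under ``config.out_dir``
    and returns the report dict.  Any stage failure raises with a
    stage-tagged message.
    """
    cfg = config
    os.makedirs(cfg.out_dir, exist_ok=True)
    resolved = cfg.resolved()
    resolved.pop("out_dir")  # output location is not computational provenance
    provenance = {
        "tool": "sweepfoot",
        "version": __version__,
        "config": resolved,
        "input_sha256": _digest(cfg.fasta),
    }
    digest = hashlib.sha256(
        json.dumps(provenance, sort_keys=True).encode()).hexdigest()[:16]

    def stage(name):
        logger.info("stage %s", name)
        return name

    name = stage("scan")
    try:
        locus = fasta_to_window(cfg.fasta, cfg.ancestral_id)
        track = sliding_scan(locus, cfg.window, cfg.step)
        name = stage("peaks")
        peaks = find_peaks(track)
        name = stage("null")
        null = build_null(NullModel(
            n=locus.n, theta_site=cfg.theta_site, rho_site=cfg.rho_site,
            L=cfg.window, reps=cfg.n_reps, seed=cfg.seed))
        name = stage("empirical_p")
        p_E = empirical_p(null["E"], peaks["E_peak"].E)
        p_H = empirical_p(null["H"], peaks["H_peak"].H)
        p_D = empirical_p(null["D"], peaks["D_peak"].D)
        name = stage("calls")
        call = call_significance(p_E, p_H, p_D, cfg.alpha)
    except SweepfootError as exc:
        raise type(exc)(f"[stage {name}] {exc}") from exc

    bed_rows = [
        ("locus", w.start, w.end, f"w{i}", 0, "+",
         w.D, w.H, w.E, w.S)
        for i, w in enumerate(track)
    ]
    write_bed(os.path.join(cfg.out_dir, "windows.bed"), bed_rows,
              header_comment=f"sweepfoot windows config={digest}",
              extra_names=["D", "H", "E", "S"])
    with open(os.path.join(cfg.out_dir, "peaks.tsv"), "w") as fh:
        fh.write(f"# sweepfoot peaks config={digest}\n")
        fh.write("statistic\tstart\tend\tvalue\n")
        for key, attr in (("E_peak", "E"), ("H_peak", "H"), ("D_peak", "D")):
            w = peaks[key]
            fh.write(f"{key}\t{w.start}\t{w.end}\t{getattr(w, attr):.6g}\n")

    report = {
        "provenance": provenance,
        "config_digest": digest,
        "n_windows": len(track),
        "peaks": {
            k: {"start": w.start, "end": w.end, "D": w.D, "H": w.H,
                "E": w.E, "S": w.S}
            for k, w in peaks.items()
        },
        "p_values": {"p_E": p_E, "p_H": p_H, "p_D": p_D},
        "calls": {
            "significant_E": call.significant_E,
            "significant_H": call.significant_H,
            "significant_D": call.significant_D,
            "sweep_flagged": call.significant_E and call.significant_H,
        },
    }
    with open(os.path.join(cfg.out_dir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
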