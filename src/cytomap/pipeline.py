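"""End-to-end pipeline: configuration, staged execution, manifest, report.

A run takes a single config (YAML/JSON-serializable dataclass), executes
the requested stages in dependency order — simulate a section, compute the
GLI image, extract and featurize profiles, detect borders — and writes
every artifact plus a manifest of SHA-256 checksums.  Identical config and
seeds reproduce identical checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as cio
from .borders import BorderConfig, detect_borders
from .gli import compute_gli_image
from .profiles import build_traverses, extract_profile, featurize_sequence, ProfileSequence
from .synthetic import (
    AnnulusSector,
    area_template,
    contours_from_truth,
    generate_profile_sequence,
    render_section_image,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "export_report"]


@dataclass
class PipelineConfig:
    """Resolved parameters of one pipeline run.

    ``mode`` selects the synthetic input: "profiles" plants the border in
    directly simulated profile sequences; "image" renders a two-area
    section, computes the GLI image and extracts profiles through the
    geometric path.
    """

    out_dir: str = "cytomap_run"
    mode: str = "image"
    seed: int = 0
    stages: tuple = ("simulate", "gli", "profiles", "borders")
    # synthetic section
    template_kinds: tuple = ("granular_dense", "dysgranular")
    n_traverses: int = 120
    segment_lengths: tuple = (60, 60)
    noise_sd: float = 0.05
    n_depth: int = 100
    resolution_um_per_px: float = 1.02
    cell_radius_um: float = 5.0
    # geometry chosen so the 120 traverses sit ~60 μm apart — farther than
    # the GLI smoothing width, keeping neighbouring profiles' noise
    # independent as the block statistics assume
    r_inner_um: float = 3000.0
    r_outer_um: float = 4200.0
    theta_span: float = 2.0
    # gli
    field_size_um: float = 17.0
    gli_smooth_fields: int = 3  # boxcar width (fields) applied to the GLI grid; <=1 disables
    # borders
    border: dict = field(default_factory=dict)

    def border_config(self) -> BorderConfig:
        return BorderConfig(**self.border) if self.border else BorderConfig()

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"invalid config field(s): {sorted(unknown)}")
        d = dict(d)
        for k in ("stages", "template_kinds", "segment_lengths"):
            if k in d and isinstance(d[k], list):
                d[k] = tuple(d[k])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def validate(self):
        if self.mode not in ("profiles", "image"):
            raise ValueError("config field 'mode' must be 'profiles' or 'image'")
        if len(self.template_kinds) != len(self.segment_lengths):
            raise ValueError("config fields 'template_kinds' and 'segment_lengths' must match")
        order = ("simulate", "gli", "profiles", "borders")
        for s in self.stages:
            if s not in order:
                raise ValueError(f"config field 'stages' contains unknown stage {s!r}")
        self.stages = tuple(s for s in order if s in self.stages)
        if self.seed is None:
            raise ValueError("config field 'seed' is required")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the configured stages and return the run directory.

    The run directory contains every stage artifact, the resolved config
    (``config.json``) and a ``manifest.json`` mapping artifact names to
    SHA-256 checksums.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    timings = {}

    seq = truth = None
    if "simulate" in config.stages:
        t = time.time()
        templates = [area_template(k) for k in config.template_kinds]
        if config.mode == "profiles":
            seq, truth = generate_profile_sequence(
                templates,
                config.segment_lengths,
                n_depth=config.n_depth,
                noise_sd=config.noise_sd,
                seed=config.seed,
            )
        else:
            geom = AnnulusSector(
                r_inner_um=config.r_inner_um,
                r_outer_um=config.r_outer_um,
                theta_start=-config.theta_span / 2,
                theta_end=config.theta_span / 2,
            )
            fracs = np.asarray(config.segment_lengths, float)
            img, truth = render_section_image(
                templates,
                geom,
                resolution_um_per_px=config.resolution_um_per_px,
                cell_radius_um=config.cell_radius_um,
                seed=config.seed,
                n_traverses=config.n_traverses,
                segment_fractions=fracs / fracs.sum(),
            )
            from PIL import Image

            Image.fromarray(img).save(out / "section.png")
        cio.write_truth(truth, out / "truth.json")
        timings["simulate"] = time.time() - t

    gli_img = None
    if "gli" in config.stages and config.mode == "image":
        t = time.time()
        from PIL import Image

        img = np.asarray(Image.open(out / "section.png"))
        gli_img = compute_gli_image(
            img,
            resolution_um_per_px=config.resolution_um_per_px,
            field_size_um=config.field_size_um,
        )
        if config.gli_smooth_fields > 1:
            # single cells per 17 μm field make raw GLI values very noisy;
            # a small boxcar over fields (~50 μm) suppresses that Poisson
            # noise while leaving the laminar pattern (layers span many
            # fields) intact
            from scipy.ndimage import uniform_filter

            import dataclasses as _dc

            gli_img = _dc.replace(
                gli_img,
                values=np.clip(
                    uniform_filter(gli_img.values, size=config.gli_smooth_fields), 0.0, 1.0
                ),
            )
        np.savetxt(out / "gli_image.csv", gli_img.values, delimiter=",", fmt="%.8g")
        (out / "gli_image.csv.json").write_text(
            json.dumps(
                {
                    "schema_version": cio.SCHEMA_VERSION,
                    "field_size_um": gli_img.field_size_um,
                    "field_px": gli_img.field_px,
                    "effective_field_size_um": gli_img.effective_field_size_um,
                    "resolution_um_per_px": gli_img.resolution_um_per_px,
                    "threshold": gli_img.threshold,
                },
                indent=1,
                sort_keys=True,
            )
        )
        timings["gli"] = time.time() - t

    if "profiles" in config.stages:
        t = time.time()
        if config.mode == "image":
            if truth is None:
                truth = cio.read_truth(out / "truth.json")
            contours = contours_from_truth(truth, config.resolution_um_per_px)
            traverses = build_traverses(contours, config.n_traverses)
            profiles = [extract_profile(gli_img, tr, config.n_depth) for tr in traverses]
            seq = ProfileSequence(
                profiles=profiles,
                arc_positions=np.asarray([tr.arc_position for tr in traverses]),
                meta={"seed": config.seed, "mode": "image"},
            )
        featurize_sequence(seq)
        cio.write_profile_sequence(seq, out / "profiles.csv", seed=config.seed)
        cio.write_features(seq.features, out / "features.csv")
        timings["profiles"] = time.time() - t

    if "borders" in config.stages:
        t = time.time()
        if seq is None:
            feats = cio.read_features(out / "features.csv")
        else:
            feats = seq.features
        result = detect_borders(feats, config.border_config())
        cio.write_border_result(result, out / "md_surface.csv", out / "borders.json")
        timings["borders"] = time.time() - t

    (out / "config.json").write_text(json.dumps(config.to_dict(), indent=1, sort_keys=True))
    artifacts = sorted(
        p for p in out.iterdir() if p.is_file() and p.name not in ("manifest.json", "report.md")
    )
    manifest = {
        "artifacts": {p.name: _sha256(p) for p in artifacts},
        "stages": list(config.stages),
        "seed": config.seed,
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
        "total_s": round(time.time() - t0, 3),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    logger.info("run complete in %.1fs: %s", time.time() - t0, out)
    return out


def export_report(run_dir) -> Path:
    """Render a human-readable markdown report (with plots) for a run.

    Missing artifacts produce warnings in the report rather than errors, so
    partial runs still yield a stub.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import pandas as pd

    run_dir = Path(run_dir)
    lines = ["# cytomap run report", ""]
    warnings = []

    cfg_path = run_dir / "config.json"
    if cfg_path.exists():
        cfg = json.loads(cfg_path.read_text())
        lines += ["## Parameters", "", "```json", json.dumps(cfg, indent=1, sort_keys=True), "```", ""]
    else:
        warnings.append("missing config.json")

    truth_path = run_dir / "truth.json"
    if truth_path.exists():
        truth = json.loads(truth_path.read_text())
        lines += [
            "## Ground truth",
            "",
            f"Planted border positions: {truth['border_positions']}",
            f"Seed: {truth.get('seed')}",
            "",
        ]

    md_path = run_dir / "md_surface.csv"
    if md_path.exists():
        df = pd.read_csv(md_path)
        fig, ax = plt.subplots(figsize=(7, 4))
        for b in sorted(df["block_size"].unique())[::4]:
            sub = df[df["block_size"] == b]
            ax.plot(sub["position"], sub["md"], label=f"block {b}")
        ax.set_xlabel("profile position")
        ax.set_ylabel("Mahalanobis D²")
        ax.legend(fontsize=8)
        fig.tight_layout()
        fig.savefig(run_dir / "md_plot.png", dpi=110)
        plt.close(fig)
        lines += ["## Mahalanobis distance", "", "![MD vs position](md_plot.png)", ""]
    else:
        warnings.append("missing md_surface.csv")

    borders_path = run_dir / "borders.json"
    if borders_path.exists():
        doc = json.loads(borders_path.read_text())
        lines += ["## Detected borders", ""]
        if doc["borders"]:
            lines += ["| position | votes | supporting block sizes |", "|---|---|---|"]
            for b in doc["borders"]:
                lines.append(f"| {b['position']} | {b['votes']} | {b['block_sizes']} |")
        else:
            lines.append("No border accepted.")
        lines.append("")
    else:
        warnings.append("missing borders.json")

    if warnings:
        lines += ["## Warnings", ""] + [f"- {w}" for w in warnings] + [""]

    report = run_dir / "report.md"
    report.write_text("\n".join(lines))
    return report
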