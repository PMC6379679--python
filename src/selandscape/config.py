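"""Run configuration: YAML parsing, validation, and defaults.

Validation is validate-then-run: every violation is collected and
reported at once, and a failing config never produces output.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from .landscape import LandscapeParams

__all__ = ["SampleSpec", "StatParams", "RunConfig", "ConfigError", "validate_config"]

_SAMPLE_CLASSES = ("cell_line", "tumor")


class ConfigError(ValueError):
    """Aggregate configuration error; one line per violation."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("invalid configuration:\n" + "\n".join(f"  - {p}" for p in problems))


@dataclass(frozen=True)
class SampleSpec:
    sample_id: str
    sample_class: str
    peaks: Path | None = None
    chip: Path | None = None
    control: Path | None = None


@dataclass(frozen=True)
class StatParams:
    min_units: int = 4
    bind_window: int = 50_000
    n_perm: int = 1000
    weight_p: float = 1.0
    fc_threshold: float = 1.0


@dataclass(frozen=True)
class RunConfig:
    outdir: Path
    seed: int = 0
    landscape: LandscapeParams = field(default_factory=LandscapeParams)
    stats: StatParams = field(default_factory=StatParams)
    samples: tuple[SampleSpec, ...] = ()
    min_cell_lines: int = 3
    min_tumors: int = 1
    simulate: Mapping[str, Any] | None = None
    genes: Path | None = None
    chrom_sizes: Path | None = None
    genome_fasta: Path | None = None
    tf_peaks: Path | None = None
    second_tf_peaks: Path | None = None
    expression_treated: Path | None = None
    expression_control: Path | None = None

    def fingerprint(self) -> str:
        """Stable hash of every parameter, stamped into output headers."""
        def enc(obj: Any) -> Any:
            if isinstance(obj, Path):
                return str(obj)
            if hasattr(obj, "__dataclass_fields__"):
                return {k: enc(getattr(obj, k)) for k in obj.__dataclass_fields__}
            if isinstance(obj, Mapping):
                return {k: enc(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [enc(v) for v in obj]
            return obj

        payload = json.dumps(enc(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _opt_path(raw: Mapping, key: str, base: Path, problems: list[str], required: bool = False) -> Path | None:
    val = raw.get(key)
    if val is None:
        if required:
            problems.append(f"{key}: required path missing")
        return None
    p = Path(val)
    if not p.is_absolute():
        p = base / p
    if not p.exists():
        problems.append(f"{key}: file not found: {p}")
    return p


def validate_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML run configuration.

    All violations (missing files, bad classes, out-of-range numbers)
    are aggregated into a single :class:`ConfigError`. Defaults are
    filled for every omitted numeric parameter.
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    base = path.parent
    problems: list[str] = []

    outdir = raw.get("outdir")
    if outdir is None:
        problems.append("outdir: required key missing")
        outdir = "."
    outdir = Path(outdir)
    if not outdir.is_absolute():
        outdir = base / outdir

    seed = raw.get("seed", 0)
    if not isinstance(seed, int):
        problems.append(f"seed: must be an integer, got {seed!r}")
        seed = 0

    lp_raw = raw.get("landscape", {}) or {}
    lp_kwargs = {}
    for key in ("stitch_distance", "tss_exclusion", "assignment_window"):
        if key in lp_raw:
            v = lp_raw[key]
            if not isinstance(v, int) or v < 0:
                problems.append(f"landscape.{key}: must be a non-negative integer, got {v!r}")
            else:
                lp_kwargs[key] = v
    landscape = LandscapeParams(**lp_kwargs)

    st_raw = raw.get("stats", {}) or {}
    st_kwargs = {}
    for key, (typ, lo) in {
        "min_units": (int, 1),
        "bind_window": (int, 0),
        "n_perm": (int, 100),
        "weight_p": ((int, float), 0),
        "fc_threshold": ((int, float), 0),
    }.items():
        if key in st_raw:
            v = st_raw[key]
            if not isinstance(v, typ) or isinstance(v, bool) or v < lo:
                problems.append(f"stats.{key}: must be >= {lo}, got {v!r}")
            else:
                st_kwargs[key] = v
    stats = StatParams(**st_kwargs)

    simulate = raw.get("simulate")
    samples: list[SampleSpec] = []
    for i, s in enumerate(raw.get("samples", []) or []):
        sid = s.get("sample_id", f"sample_{i}")
        klass = s.get("class", s.get("sample_class"))
        if klass not in _SAMPLE_CLASSES:
            problems.append(
                f"samples[{i}].class: {klass!r} not in {_SAMPLE_CLASSES}"
            )
            klass = "cell_line"
        if simulate is None:
            peaks = _opt_path(s, "peaks", base, problems, required=True)
            chip = _opt_path(s, "chip", base, problems, required=True)
            control = _opt_path(s, "control", base, problems)
        else:
            peaks = chip = control = None
        samples.append(
            SampleSpec(sample_id=sid, sample_class=klass, peaks=peaks, chip=chip, control=control)
        )

    kwargs: dict[str, Any] = {}
    if simulate is None:
        for key in (
            "genes",
            "chrom_sizes",
            "genome_fasta",
            "tf_peaks",
            "second_tf_peaks",
            "expression_treated",
            "expression_control",
        ):
            kwargs[key] = _opt_path(raw, key, base, problems)
        if not samples:
            problems.append("samples: at least one sample (or a simulate block) is required")
    else:
        if not isinstance(simulate, Mapping):
            problems.append("simulate: must be a mapping of SimConfig overrides")
            simulate = {}
        else:
            from .simulate import SimConfig

            valid = set(SimConfig.__dataclass_fields__)
            for k in simulate:
                if k not in valid:
                    problems.append(f"simulate.{k}: unknown SimConfig field")

    if problems:
        raise ConfigError(problems)
    return RunConfig(
        outdir=outdir,
        seed=seed,
        landscape=landscape,
        stats=stats,
        samples=tuple(samples),
        min_cell_lines=raw.get("min_cell_lines", 3),
        min_tumors=raw.get("min_tumors", 1),
        simulate=simulate,
        **kwargs,
    )
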