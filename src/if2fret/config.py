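"""Configuration models for the smFRET simulation and analysis pipeline.

Two layers of configuration exist:

* :class:`SimulationConfig` — everything the trajectory generator needs for a
  single condition (rate constants, emission model, photophysics, noise,
  dataset size, seed).
* :class:`ConditionConfig` — a named experimental condition (e.g. the
  wild-type IF2(GTP) 30S initiation complex) with its generating kinetics,
  bound-state FRET substates and the photobleaching corrections the analysis
  applies to it.

The eight bundled conditions and the published values they are compared
against live in ``data/reference_values.json`` and are exposed through
:func:`reference_values` and :func:`bundled_conditions`.
"""

from __future__ import annotations

import json
from importlib import resources
from functools import lru_cache
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

#: Acquisition interval of the emulated TIRF movies, seconds per frame.
DEFAULT_FRAME_TIME = 0.1

#: Free IF2 concentration in solution, µM (25 nM in the imaging buffer).
DEFAULT_IF2_CONC = 0.025

#: FRET-efficiency threshold separating the IF2-free (E <= 0.2, inclusive)
#: from the IF2-bound (E > 0.2) macro-state.
FREE_EFRET_THRESHOLD = 0.2

#: Förster distance of the Cy3-Cy5 pair, Å.
DEFAULT_R0 = 55.0


class Substate(BaseModel):
    """One bound-state FRET subpopulation: mean efficiency, width, weight."""

    mean: float = Field(ge=0.0, le=1.0)
    width: float = Field(ge=0.0)
    weight: float = Field(ge=0.0, le=1.0)


class SimulationConfig(BaseModel):
    """Parameters of the synthetic two-channel smFRET trajectory generator.

    Rates are first-order (s⁻¹) except ``k_a`` which is bimolecular
    (µM⁻¹ s⁻¹); the pseudo-first-order binding rate is ``k_a * if2_conc``.
    Intensities are in arbitrary camera units.
    """

    k_a: float = Field(default=2.0, ge=0.0, description="association rate, µM⁻¹ s⁻¹")
    if2_conc: float = Field(default=DEFAULT_IF2_CONC, ge=0.0, description="free IF2, µM")
    k_d: float = Field(default=0.041, ge=0.0, description="dissociation rate, s⁻¹")
    frame_time: float = Field(default=DEFAULT_FRAME_TIME, gt=0.0, description="s/frame")
    # 180 s observation window: the transition-matrix estimator needs the
    # window to be long compared to the slowest mean dwell (~24 s bound for
    # the wild-type GTP condition), otherwise censoring of final dwells
    # dominates the counting statistics.
    n_frames: int = Field(default=1800, ge=1)
    substates: list[Substate] = Field(
        default_factory=lambda: [Substate(mean=0.87, width=0.05, weight=1.0)]
    )
    free_efret_mean: float = 0.0
    free_efret_width: float = Field(default=0.05, ge=0.0)
    total_intensity: float = Field(default=1000.0, gt=0.0)
    bleedthrough: float = Field(default=0.07, ge=0.0, lt=1.0)
    noise_sd: float = Field(default=80.0, ge=0.0, description="per-channel additive sd, a.u.")
    kb_cy3: float = Field(default=0.005, ge=0.0, description="donor bleach rate, s⁻¹")
    kb_cy5: float = Field(default=0.01, ge=0.0, description="acceptor bleach rate, s⁻¹")
    # Cy5 rides the exchanging IF2 molecule, so by default each binding event
    # carries a fresh acceptor and the bleach clock restarts at dwell entry.
    # "per_trace" runs a single clock from t=0 (one shared acceptor).
    cy5_bleach_mode: Literal["per_event", "per_trace"] = "per_event"
    # Optional intra-dwell substate interconversion rate (s⁻¹); off by
    # default because positions interconverting faster than the frame time
    # are indistinguishable from a fixed average position at this resolution.
    substate_switch_rate: float = Field(default=0.0, ge=0.0)
    n_traces: int = Field(default=150, ge=0)
    n_replicates: int = Field(default=3, ge=1)
    seed: int = 0

    @field_validator("k_a", "k_d", "if2_conc", "noise_sd", "kb_cy3", "kb_cy5")
    @classmethod
    def _finite(cls, v: float) -> float:
        if not (v == v and abs(v) != float("inf")):
            raise ValueError("rates and noise levels must be finite")
        return v

    @model_validator(mode="after")
    def _weights_sum_to_one(self) -> "SimulationConfig":
        total = sum(s.weight for s in self.substates)
        if self.substates and abs(total - 1.0) > 1e-9:
            raise ValueError(f"substate weights must sum to 1 (got {total!r})")
        return self

    @property
    def pseudo_first_order_rate(self) -> float:
        """Free→bound rate ``k_a * [IF2]`` in s⁻¹."""
        return self.k_a * self.if2_conc

    @property
    def duration(self) -> float:
        """Trajectory span in seconds."""
        return self.n_frames * self.frame_time


class ConditionConfig(BaseModel):
    """A named 30S IC condition: generating kinetics plus analysis toggles."""

    name: str
    label: str = ""
    k_a: float = Field(ge=0.0)
    k_d: float = Field(ge=0.0)
    substates: list[Substate]
    exclude_final_free_dwell: bool = False
    pad_cy3: bool = False
    reference: Optional[str] = None
    sim_overrides: dict = Field(default_factory=dict)

    @model_validator(mode="after")
    def _padding_needs_reference(self) -> "ConditionConfig":
        if self.pad_cy3 and not self.reference:
            raise ValueError(f"condition {self.name!r} pads Cy3 but names no reference")
        total = sum(s.weight for s in self.substates)
        if self.substates and abs(total - 1.0) > 1e-9:
            raise ValueError(f"substate weights must sum to 1 (got {total!r})")
        return self

    def simulation_config(self, **overrides) -> SimulationConfig:
        """Build the generator configuration for this condition."""
        kwargs = dict(k_a=self.k_a, k_d=self.k_d, substates=self.substates)
        kwargs.update(self.sim_overrides)
        kwargs.update(overrides)
        return SimulationConfig(**kwargs)


@lru_cache(maxsize=1)
def reference_values() -> dict:
    """Published reference values bundled with the package (read-only)."""
    text = resources.files("if2fret").joinpath("data/reference_values.json").read_text()
    return json.loads(text)


def bundled_conditions() -> dict[str, ConditionConfig]:
    """The eight bundled 30S IC conditions, keyed by short name.

    Generating rate constants come from the published kinetic table; the
    bound-state substate means and weights from the published histogram
    decompositions. Corrections mirror the published analysis: the
    final-free-dwell (Cy5) exclusion for the two long-lived GTP conditions,
    zero-FRET trace padding (Cy3 correction) for the two rare-event
    pseudo-complex conditions, with the wild-type GTP condition as the
    binding-capable reference.
    """
    ref = reference_values()
    out: dict[str, ConditionConfig] = {}
    for name, c in ref["conditions"].items():
        # conformational (per-dwell) width is small: the published peak
        # widths are dominated by per-frame measurement noise, which the
        # generator adds at the channel level
        substates = [
            Substate(mean=p["mean"], width=p.get("sim_width", 0.02), weight=p["weight"])
            for p in c["peaks"]
        ]
        out[name] = ConditionConfig(
            name=name,
            label=c["label"],
            k_a=c["k_a"],
            k_d=c["k_d"],
            substates=substates,
            exclude_final_free_dwell="cy5" in c["corrections"],
            pad_cy3="cy3" in c["corrections"],
            reference=c.get("reference"),
        )
    return out


def load_conditions(path) -> list[ConditionConfig]:
    """Parse and validate a YAML condition file.

    The file maps condition names to :class:`ConditionConfig` fields; a
    ``defaults`` block is merged into every condition. Cross-references
    (``reference`` of a padded condition) must name a condition in the file.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    defaults = raw.pop("defaults", {})
    conditions: list[ConditionConfig] = []
    errors: list[str] = []
    for name, body in raw.items():
        merged = {**defaults, **(body or {}), "name": name}
        try:
            conditions.append(ConditionConfig(**merged))
        except Exception as exc:  # collect all schema violations
            errors.append(f"{name}: {exc}")
    names = {c.name for c in conditions}
    for c in conditions:
        if c.reference is not None and c.reference not in names:
            errors.append(f"{c.name}: unknown reference condition {c.reference!r}")
    if len(names) != len(conditions):
        errors.append("condition names must be unique")
    if errors:
        raise ValueError("invalid condition file:\n" + "\n".join(errors))
    return conditions
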