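"""SNP-like model variants: channel-parameter deltas, downscaling, combination.

A *model variant* stands in for the effect of a single-nucleotide polymorphism
on an ion channel: a named set of deltas on channel-gate parameters
(half-activation shift in mV, slope / time-constant / conductance factors).
Literature-derived full effects are typically far too strong to represent a
common small-effect allele, so each variant is attenuated by a coefficient
c ∈ (0, 1] — linearly for additive mV shifts, on a logarithmic scale for
multiplicative factors — until the cell's response to a fixed step-current
protocol stays within an acceptance band around the unmodified cell
(:func:`downscale`).  Variants combine by linear superposition on channel
parameters: shifts add, factors multiply.

Because the original literature-derived variant tables are not part of this
repository, the bundled library (``data/variants_synthetic.tsv``) is a
*synthetic* representative set of 86 variants spanning all parameter classes,
with four named exemplars (Ca7, Ca74, HCN1-1, HCN1-2) matching the
qualitative descriptions of the strongest gamma-reducing variants.  A blank
schema template (``data/variants_template.tsv``) is provided for transcribing
real tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .cells import CellSpec, FeatureVector, StepProtocol, data_path, extract_features
from .channels import IDENTITY_MODIFIER, KineticModifier

__all__ = [
    "GENES",
    "TARGET_CHANNELS",
    "ParamDelta",
    "VariantSpec",
    "ScaledVariant",
    "FeatureBands",
    "VariantTableError",
    "VariantUnusableError",
    "load_variant_table",
    "save_variant_table",
    "scale_variant",
    "combine_variants",
    "apply_variant",
    "downscale",
    "features_within",
    "synthesize_variant_library",
    "load_bundled_variants",
]

#: Accepted gene labels.  Both HCN1 and HCN1A are accepted (the literature
#: uses both spellings for the same target), as are the Ca²⁺ subunit genes.
GENES = ("CACNA1C", "CACNA1D", "CACNB2", "CACNA1I", "SCN1A", "HCN1", "HCN1A")
TARGET_CHANNELS = ("CaHVA", "CaLVA", "Ih", "NaT", "NaP")
PARAM_CLASSES = ("dv_shift", "slope_factor", "tau_factor", "g_factor")
_FACTOR_CLASSES = ("slope_factor", "tau_factor", "g_factor")


class VariantTableError(ValueError):
    """Raised for malformed variant tables, with row-level context."""


class VariantUnusableError(RuntimeError):
    """Raised when a variant fails the acceptance criteria even as c → 0."""


@dataclass(frozen=True)
class ParamDelta:
    """One full-effect parameter change.  ``gate`` is a gate label (m, h) or
    ``'-'`` for channel-level (g_factor) deltas."""

    gate: str
    param_class: str
    value: float

    def __post_init__(self):
        if self.param_class not in PARAM_CLASSES:
            raise ValueError(f"unknown parameter class {self.param_class!r}")
        if self.param_class in _FACTOR_CLASSES and self.value <= 0:
            raise ValueError(
                f"{self.param_class} delta must be > 0, got {self.value}"
            )
        if not np.isfinite(self.value):
            raise ValueError("delta value must be finite")

    def scaled(self, c: float) -> float:
        """Linear scaling for mV shifts, logarithmic for factors."""
        if self.param_class == "dv_shift":
            return c * self.value
        return float(self.value**c)


@dataclass(frozen=True)
class VariantSpec:
    id: str
    gene: str
    target_channel: str
    deltas: tuple[ParamDelta, ...]
    provenance: str = ""

    def __post_init__(self):
        if self.gene not in GENES:
            raise ValueError(f"unknown gene {self.gene!r}; accepted: {GENES}")
        if self.target_channel not in TARGET_CHANNELS:
            raise ValueError(
                f"unknown target channel {self.target_channel!r}; "
                f"accepted: {TARGET_CHANNELS}"
            )
        if not self.deltas:
            raise ValueError(f"variant {self.id}: needs at least one delta")


def _modifiers_from_deltas(
    channel: str, deltas: Sequence[tuple[str, str, float]]
) -> dict[str, dict[str, KineticModifier]]:
    """Collapse (gate, class, value) triples into per-channel modifier maps.

    Returns ``{channel: {gate_or_'-': KineticModifier}}``; the ``'-'`` entry
    carries channel-level g_factor.
    """
    per_gate: dict[str, dict[str, float]] = {}
    for gate, cls, value in deltas:
        slot = per_gate.setdefault(gate, {})
        if cls == "dv_shift":
            slot["dv_shift"] = slot.get("dv_shift", 0.0) + value
        else:
            slot[cls] = slot.get(cls, 1.0) * value
    out = {}
    for gate, kw in per_gate.items():
        out[gate] = KineticModifier(**kw)
    return {channel: out}


@dataclass(frozen=True)
class ScaledVariant:
    """A variant attenuated to coefficient ``c``, in directly applicable form.

    ``effective_modifiers`` maps channel name → {gate label or '-' →
    KineticModifier}; c = 1 reproduces the full literature effect and c → 0
    approaches identity.
    """

    base: Optional[VariantSpec]
    coefficient: float
    effective_modifiers: Mapping[str, Mapping[str, KineticModifier]]
    label: str = ""

    def __post_init__(self):
        if not (0 < self.coefficient <= 1):
            raise ValueError(f"coefficient must be in (0, 1], got {self.coefficient}")

    @property
    def id(self) -> str:
        return self.label or (self.base.id if self.base else "composite")


def scale_variant(variant: VariantSpec, c: float) -> ScaledVariant:
    """Attenuate ``variant`` to coefficient ``c`` ∈ (0, 1].

    mV shifts scale linearly (c·Δv); slope, τ and ḡ factors scale
    logarithmically (factor^c), so c = 0.5 turns a 4-fold τ change into a
    2-fold one.  Deterministic and exact.
    """
    if not (0 < c <= 1):
        raise ValueError(f"coefficient must be in (0, 1], got {c}")
    triples = [(d.gate, d.param_class, d.scaled(c)) for d in variant.deltas]
    mods = _modifiers_from_deltas(variant.target_channel, triples)
    return ScaledVariant(
        base=variant, coefficient=float(c), effective_modifiers=mods,
        label=variant.id,
    )


def combine_variants(variants: Sequence[ScaledVariant]) -> ScaledVariant:
    """Linear superposition of scaled variants on channel parameters.

    Per (channel, gate): voltage shifts add and factors multiply, so the
    operation is commutative and associative by construction.  Combining a
    variant with itself doubles every shift and squares every factor.
    """
    variants = list(variants)
    if not variants:
        raise ValueError("cannot combine an empty list of variants")
    merged: dict[str, dict[str, KineticModifier]] = {}
    for sv in variants:
        for chan, gates in sv.effective_modifiers.items():
            slot = merged.setdefault(chan, {})
            for gate, mod in gates.items():
                slot[gate] = slot.get(gate, IDENTITY_MODIFIER).compose(mod)
    label = "+".join(sv.id for sv in variants)
    coeff = max(sv.coefficient for sv in variants)
    return ScaledVariant(
        base=None, coefficient=coeff, effective_modifiers=merged, label=label
    )


def apply_variant(cell: CellSpec, sv: ScaledVariant) -> CellSpec:
    """Return a copy of ``cell`` with the variant's modifiers composed on.

    The original cell is untouched.  Raises if a target channel is absent.
    """
    missing = set(sv.effective_modifiers) - cell.channel_names
    if missing:
        raise ValueError(
            f"variant {sv.id} targets channels absent from the cell: "
            f"{sorted(missing)}"
        )
    new_comps = []
    for comp in cell.compartments:
        chans = []
        for ch in comp.channels:
            if ch.name in sv.effective_modifiers:
                gates = dict(sv.effective_modifiers[ch.name])
                chan_mod = gates.pop("-", None)
                if chan_mod is not None:
                    ch = ch.with_modifier(chan_mod)
                if gates:
                    ch = ch.with_gate_modifiers(gates)
            chans.append(ch)
        new_comps.append(replace(comp, channels=tuple(chans)))
    return replace(cell, compartments=tuple(new_comps))


# ---------------------------------------------------------------------------
# Downscaling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureBands:
    """Acceptance band around the unmodified cell's feature vector.

    Defaults: each spike count within ±10 % (at least ±1 spike) of control,
    resting potential within ±2 mV, input resistance within ±10 %.
    """

    spike_count_rel: float = 0.10
    spike_count_min: int = 1
    resting_mv: float = 2.0
    input_resistance_rel: float = 0.10
    protocol: StepProtocol = field(default_factory=StepProtocol)


def features_within(candidate: FeatureVector, control: FeatureVector,
                    bands: FeatureBands) -> bool:
    """True if ``candidate`` lies inside the acceptance band around ``control``."""
    for got, ref in zip(candidate.spike_counts, control.spike_counts):
        tol = max(bands.spike_count_min, bands.spike_count_rel * ref)
        if abs(got - ref) > tol:
            return False
    if abs(candidate.resting_v - control.resting_v) > bands.resting_mv:
        return False
    rin_tol = bands.input_resistance_rel * abs(control.input_resistance)
    if abs(candidate.input_resistance - control.input_resistance) > rin_tol:
        return False
    return True


def downscale(
    variant: VariantSpec,
    cell: CellSpec,
    criteria: FeatureBands | None = None,
    evaluate: Callable[[float], bool] | None = None,
    resolution: float = 1e-3,
    coarse_points: int = 8,
) -> ScaledVariant:
    """Find the largest coefficient keeping cell features inside the bands.

    ``evaluate(c) -> bool`` decides whether coefficient ``c`` passes; by
    default it simulates the step protocol on the variant-modified cell and
    checks :func:`features_within` against the unmodified cell.  A custom
    evaluator supports testing the search against cheap oracles.

    The pass/fail boundary need not be monotone in c (features can cross a
    band edge and come back), so the search is deviation-tolerant: a coarse
    descending scan over ``coarse_points`` coefficients locates the largest
    passing point, then bisection against its failing upper neighbour refines
    the boundary to ``resolution``.  If the full effect (c = 1) already
    passes, c = 1 is returned.  A variant failing even at c = ``resolution``
    is reported as unusable.
    """
    if evaluate is None:
        bands = criteria or FeatureBands()
        control = extract_features(cell, bands.protocol)

        def evaluate(c: float) -> bool:
            modified = apply_variant(cell, scale_variant(variant, c))
            fv = extract_features(modified, bands.protocol)
            return features_within(fv, control, bands)

    if evaluate(1.0):
        return scale_variant(variant, 1.0)

    grid = np.linspace(1.0, 1.0 / coarse_points, coarse_points)
    lo, hi = None, 1.0
    for c in grid[1:]:
        if evaluate(float(c)):
            lo = float(c)
            break
        hi = float(c)
    if lo is None:
        if evaluate(resolution):
            lo, hi = resolution, float(grid[-1])
        else:
            raise VariantUnusableError(
                f"variant {variant.id} fails the acceptance criteria even at "
                f"c = {resolution}; flagged unusable"
            )
    while hi - lo > resolution:
        mid = 0.5 * (lo + hi)
        if evaluate(mid):
            lo = mid
        else:
            hi = mid
    return scale_variant(variant, lo)


# ---------------------------------------------------------------------------
# Variant tables
# ---------------------------------------------------------------------------

_TABLE_COLUMNS = ["id", "gene", "channel", "gate", "param_class", "value", "provenance"]


def load_variant_table(path, cell: CellSpec | None = None) -> list[VariantSpec]:
    """Load a TSV/CSV variant table into validated :class:`VariantSpec`s.

    Schema: ``id  gene  channel  gate  param_class  value  provenance`` with
    one row per delta; rows of one variant must agree on gene and channel.
    Errors carry the offending line number.  If ``cell`` is given, every
    (channel, gate) pair is additionally checked against the cell.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep, comment="#", dtype=str)
    if list(df.columns) != _TABLE_COLUMNS:
        raise VariantTableError(
            f"{path}: expected columns {_TABLE_COLUMNS}, got {list(df.columns)}"
        )
    errors: list[str] = []
    groups: dict[str, dict] = {}
    for idx, row in df.iterrows():
        line = idx + 2
        vid = str(row["id"]).strip()
        try:
            gene = str(row["gene"]).strip()
            chan = str(row["channel"]).strip()
            gate = str(row["gate"]).strip()
            cls = str(row["param_class"]).strip()
            value = float(row["value"])
            delta = ParamDelta(gate=gate, param_class=cls, value=value)
            if cls == "g_factor" and gate != "-":
                raise ValueError("g_factor rows must use gate '-'")
            if cls != "g_factor" and gate == "-":
                raise ValueError(f"{cls} rows must name a gate")
            slot = groups.setdefault(
                vid, {"gene": gene, "channel": chan, "deltas": [],
                      "provenance": str(row.get("provenance", "") or "")}
            )
            if slot["gene"] != gene or slot["channel"] != chan:
                raise ValueError(
                    f"variant {vid}: inconsistent gene/channel across rows"
                )
            slot["deltas"].append(delta)
        except (ValueError, TypeError) as exc:
            errors.append(f"{path.name}:{line}: {exc}")
    variants = []
    for vid, slot in groups.items():
        try:
            v = VariantSpec(
                id=vid, gene=slot["gene"], target_channel=slot["channel"],
                deltas=tuple(slot["deltas"]), provenance=slot["provenance"],
            )
            if cell is not None:
                sv = scale_variant(v, 1.0)
                apply_variant(cell, sv)  # validates channel/gate existence
            variants.append(v)
        except ValueError as exc:
            errors.append(f"{path.name}: variant {vid}: {exc}")
    if errors:
        raise VariantTableError("\n".join(errors))
    ids = [v.id for v in variants]
    if len(set(ids)) != len(ids):
        raise VariantTableError(f"{path}: duplicate variant ids")
    return variants


def save_variant_table(variants: Sequence[VariantSpec], path) -> None:
    rows = []
    for v in variants:
        for d in v.deltas:
            rows.append(
                dict(id=v.id, gene=v.gene, channel=v.target_channel,
                     gate=d.gate, param_class=d.param_class, value=d.value,
                     provenance=v.provenance)
            )
    pd.DataFrame(rows, columns=_TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Synthetic representative library
# ---------------------------------------------------------------------------

#: Named exemplars.  Ca7 and Ca74 are excitability-reducing Ca-channel
#: variants (activation left-shift → more Ca²⁺ influx → stronger SK
#: afterhyperpolarization); HCN1-1/-2 hyperpolarize the Ih activation curve
#: (negative offset shift, increased slope factor), lowering resting
#: excitability.  HCN1-2 is the stronger of the two.
_EXEMPLARS = [
    ("Ca7", "CACNA1C", "CaHVA",
     [("m", "dv_shift", -10.0), ("-", "g_factor", 1.4)]),
    ("Ca74", "CACNA1I", "CaLVA",
     [("m", "dv_shift", -8.0), ("-", "g_factor", 1.3)]),
    ("HCN1-1", "HCN1", "Ih",
     [("m", "dv_shift", -6.0), ("m", "slope_factor", 1.3)]),
    ("HCN1-2", "HCN1", "Ih",
     [("m", "dv_shift", -10.0), ("m", "slope_factor", 1.5)]),
]

_FAMILIES = [
    # (gene, channel, count excluding exemplars)
    ("CACNA1C", "CaHVA", 19),
    ("CACNA1D", "CaHVA", 12),
    ("CACNB2", "CaHVA", 10),
    ("CACNA1I", "CaLVA", 11),
    ("SCN1A", "NaT", 12),
    ("SCN1A", "NaP", 6),
    ("HCN1", "Ih", 12),
]


def synthesize_variant_library(seed: int = 20220428) -> list[VariantSpec]:
    """Generate the synthetic 86-variant representative library.

    Deterministic given ``seed``.  Full-effect deltas are drawn in ranges
    typical of the heterologous-expression literature this kind of table is
    transcribed from: activation/inactivation offsets of a few to ~15 mV,
    slope and τ factors of 0.5–2.5, conductance factors of 0.5–2.  Every
    parameter class occurs, and the four named exemplars are fixed.
    """
    rng = np.random.default_rng(seed)
    variants = [
        VariantSpec(
            id=vid, gene=gene, target_channel=chan,
            deltas=tuple(ParamDelta(g, c, v) for g, c, v in deltas),
            provenance="synthetic exemplar",
        )
        for vid, gene, chan, deltas in _EXEMPLARS
    ]
    counters: dict[str, int] = {}
    for gene, chan, count in _FAMILIES:
        for _ in range(count):
            k = counters.get(gene, 0) + 1
            counters[gene] = k
            vid = f"{gene}-s{k}"
            gates = ("m", "h") if chan != "Ih" else ("m",)
            n_deltas = int(rng.integers(1, 4))
            deltas = []
            used = set()
            for _ in range(n_deltas):
                cls = rng.choice(PARAM_CLASSES)
                gate = "-" if cls == "g_factor" else str(rng.choice(gates))
                if (gate, cls) in used:
                    continue
                used.add((gate, cls))
                if cls == "dv_shift":
                    value = float(rng.uniform(2.0, 15.0) * rng.choice([-1, 1]))
                elif cls == "tau_factor":
                    value = float(np.exp(rng.uniform(np.log(0.5), np.log(2.5))))
                elif cls == "slope_factor":
                    value = float(np.exp(rng.uniform(np.log(0.6), np.log(1.8))))
                else:
                    value = float(np.exp(rng.uniform(np.log(0.5), np.log(2.0))))
                deltas.append(ParamDelta(gate, cls, value))
            variants.append(
                VariantSpec(
                    id=vid, gene=gene, target_channel=chan,
                    deltas=tuple(deltas), provenance=f"synthetic (seed {seed})",
                )
            )
    assert len(variants) == 86
    return variants


def load_bundled_variants(cell: CellSpec | None = None) -> list[VariantSpec]:
    """The shipped synthetic 86-variant library."""
    return load_variant_table(data_path("variants_synthetic.tsv"), cell=cell)


def get_variant(variants: Sequence[VariantSpec], vid: str) -> VariantSpec:
    for v in variants:
        if v.id == vid:
            return v
    raise KeyError(f"no variant with id {vid!r}")
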