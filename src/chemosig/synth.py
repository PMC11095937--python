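"""Seeded synthetic data with known ground truth.

Two generators are provided:

* :func:`simulate_traces` draws a population of vomeronasal sensory neurons
  with planted response classes (nonresponsive, K_only, specialist_A/B,
  generalist) and renders their dF/F traces against a stimulus protocol:
  stimulus-locked difference-of-exponential transients, a terminal K+
  transient for every depolarization-sensitive class, multiplicative
  presentation-to-presentation reliability jitter and additive Gaussian
  noise.
* :func:`simulate_compound_table` draws a compounds x samples abundance
  table over the six sex/strain groups with planted presence-pattern
  categories (generic, sex-specific, strain-specific, combination-exclusive,
  uncategorized), negative-binomial abundances, per-group concentration
  biases and per-sample detection dropout.

Both are deterministic given their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chem import (
    CAT_EXCLUSIVE,
    CAT_GENERIC,
    CAT_SEX,
    CAT_STRAIN,
    CAT_UNCATEGORIZED,
    GROUPS,
    SEXES,
    STRAINS,
    CompoundTable,
    group_token,
)
from .protocol import K_LABEL, StimulusProtocol, make_protocol
from .traces import NEURON_CLASSES, TraceSet

__all__ = [
    "AmplitudeModel",
    "PopulationSpec",
    "CompoundDesign",
    "simulate_traces",
    "simulate_compound_table",
    "lipocalin_design",
    "make_protocol",
]


# ---------------------------------------------------------------------------
# trace simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AmplitudeModel:
    """Truncated-normal amplitude distribution (mean, sd, lower floor)."""

    mean: float
    sd: float
    floor: float

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return np.maximum(rng.normal(self.mean, self.sd, size=n), self.floor)


#: Default class mix: 92% of ROIs are depolarization (K+) sensitive, 38.4% of
#: those respond to urine, and 61.4% of urine responders are generalists with
#: the specialist remainder split evenly -- the composition reported for large
#: VSN populations.
DEFAULT_CLASS_FRACTIONS = {
    "nonresponsive": 0.08,
    "K_only": 0.567,
    "specialist_A": 0.068,
    "specialist_B": 0.068,
    "generalist": 0.217,
}


@dataclass
class PopulationSpec:
    """Parameters of a simulated VSN population."""

    n_neurons: int = 500
    class_fractions: dict = field(
        default_factory=lambda: dict(DEFAULT_CLASS_FRACTIONS)
    )
    k_amplitude: AmplitudeModel = AmplitudeModel(1.0, 0.15, 0.6)
    response_amplitude: AmplitudeModel = AmplitudeModel(0.5, 0.15, 0.2)
    ri_sd: float = 0.2
    ri_clip: float = 0.6
    noise_sd: float = 0.02
    rise_s: float = 2.0
    decay_s: float = 8.0
    reliability_jitter: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_neurons < 0:
            raise ValueError("n_neurons must be >= 0")
        if abs(sum(self.class_fractions.values()) - 1.0) > 1e-9:
            raise ValueError("class_fractions must sum to 1")
        if set(self.class_fractions) - set(NEURON_CLASSES):
            raise ValueError(f"unknown classes in {set(self.class_fractions)}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.rise_s <= 0 or self.decay_s <= 0:
            raise ValueError("transient kinetics must be > 0")
        if self.reliability_jitter < 0:
            raise ValueError("reliability_jitter must be >= 0")


def _transient_kernel(t_rel: np.ndarray, rise_s: float, decay_s: float) -> np.ndarray:
    """Unit-peak difference-of-exponentials transient, zero before onset."""
    t = np.clip(t_rel, 0.0, None)
    shape = (1.0 - np.exp(-t / rise_s)) * np.exp(-t / decay_s)
    t_peak = rise_s * math.log1p(decay_s / rise_s)
    peak = (1.0 - math.exp(-t_peak / rise_s)) * math.exp(-t_peak / decay_s)
    out = shape / peak
    out[t_rel < 0] = 0.0
    return out


def _allocate_classes(fractions: dict, n: int) -> list[str]:
    """Largest-remainder allocation so class counts are exact, order fixed."""
    classes = [c for c in NEURON_CLASSES if fractions.get(c, 0) > 0]
    raw = {c: fractions[c] * n for c in classes}
    counts = {c: int(math.floor(raw[c])) for c in classes}
    short = n - sum(counts.values())
    for c in sorted(classes, key=lambda c: raw[c] - counts[c], reverse=True)[:short]:
        counts[c] += 1
    out: list[str] = []
    for c in classes:
        out.extend([c] * counts[c])
    return out


def simulate_traces(
    protocol: StimulusProtocol | None = None,
    spec: PopulationSpec | None = None,
) -> tuple[TraceSet, pd.DataFrame]:
    """Render a seeded synthetic trace population with ground truth.

    Returns a :class:`TraceSet` and a ground-truth table with one row per
    ROI: true_class, true_ri (NaN outside generalists), the K+ amplitude and
    the intended K+-normalized amplitude per stimulus.
    """
    protocol = protocol or make_protocol()
    spec = spec or PopulationSpec()
    rng = np.random.default_rng(spec.seed)

    stim_labels = protocol.stimulus_labels
    if len(stim_labels) != 2:
        raise ValueError("trace simulation expects a two-stimulus protocol")
    stim_a, stim_b = stim_labels

    n = spec.n_neurons
    dt = 1.0 / protocol.sampling_rate_hz
    time = np.arange(0.0, protocol.total_duration_s + 0.5 * dt, dt)

    classes = np.array(_allocate_classes(spec.class_fractions, n), dtype=object)
    rng.shuffle(classes)

    k_amp = spec.k_amplitude.draw(rng, n)
    overall = spec.response_amplitude.draw(rng, n)
    true_ri = np.clip(rng.normal(0.0, spec.ri_sd, size=n), -spec.ri_clip, spec.ri_clip)

    amp_a = np.zeros(n)
    amp_b = np.zeros(n)
    for i, cls in enumerate(classes):
        if cls == "generalist":
            amp_a[i] = overall[i] * (1.0 + true_ri[i])
            amp_b[i] = overall[i] * (1.0 - true_ri[i])
        elif cls == "specialist_A":
            amp_a[i] = overall[i]
        elif cls == "specialist_B":
            amp_b[i] = overall[i]
        if cls not in ("generalist",):
            true_ri[i] = np.nan

    dff = np.zeros((n, time.size))
    for ev in protocol.events:
        kernel = _transient_kernel(time - ev.onset_s, spec.rise_s, spec.decay_s)
        if ev.label == K_LABEL:
            amp = np.where(classes == "nonresponsive", 0.0, k_amp)
        elif ev.label == stim_a:
            amp = amp_a * k_amp
        else:
            amp = amp_b * k_amp
        jitter = (
            np.clip(rng.normal(1.0, spec.reliability_jitter, size=n), 0.0, None)
            if spec.reliability_jitter > 0
            else np.ones(n)
        )
        dff += np.outer(amp * jitter, kernel)

    if spec.noise_sd > 0:
        dff += rng.normal(0.0, spec.noise_sd, size=dff.shape)

    roi_ids = [f"roi_{i:04d}" for i in range(n)]
    truth = pd.DataFrame(
        {
            "roi_id": roi_ids,
            "true_class": classes,
            "true_ri": true_ri,
            "k_amplitude": np.where(classes == "nonresponsive", 0.0, k_amp),
            f"amp_{stim_a}": amp_a,
            f"amp_{stim_b}": amp_b,
        }
    )
    traces = TraceSet(
        time_s=time,
        dff=dff,
        roi_ids=roi_ids,
        meta={"seed": spec.seed, "stimuli": list(stim_labels)},
    )
    return traces, truth


# ---------------------------------------------------------------------------
# compound table simulation
# ---------------------------------------------------------------------------

#: Default planted category counts (keys are category tokens; exclusive and
#: strain-specific counts apply to *each* group/strain).
DEFAULT_CATEGORY_COUNTS = {
    CAT_GENERIC: 48,
    f"{CAT_SEX}:male": 8,
    f"{CAT_SEX}:female": 8,
    **{f"{CAT_STRAIN}:{s}": 4 for s in STRAINS},
    **{f"{CAT_EXCLUSIVE}:{g}": 6 for g in GROUPS},
    CAT_UNCATEGORIZED: 12,
}


@dataclass
class CompoundDesign:
    """Planted design for a six-group sample x compound abundance table."""

    n_samples_per_group: int = 10
    category_counts: dict = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_COUNTS)
    )
    nb_mean: float = 100.0
    nb_dispersion: float = 1.0
    mean_spread_log10: float = 0.3
    detection_dropout: float = 0.1
    concentration_bias: dict = field(default_factory=dict)
    contamination_rate: float = 0.0
    voc_fraction: float = 0.5
    family: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples_per_group <= 0:
            raise ValueError("n_samples_per_group must be > 0")
        if any(v < 0 for v in self.category_counts.values()):
            raise ValueError("category counts must be >= 0")
        if not 0.0 <= self.detection_dropout <= 1.0:
            raise ValueError("detection_dropout must be in [0, 1]")
        if not 0.0 <= self.contamination_rate <= 1.0:
            raise ValueError("contamination_rate must be in [0, 1]")
        if self.nb_mean < 0 or self.nb_dispersion <= 0:
            raise ValueError("nb_mean must be >= 0 and nb_dispersion > 0")
        for g, b in self.concentration_bias.items():
            if g not in GROUPS:
                raise ValueError(f"unknown group in concentration_bias: {g!r}")
            if b < 0:
                raise ValueError("bias factors must be >= 0")


def _category_pattern(category: str, variant: int) -> frozenset:
    """Groups in which a compound of the given planted category is present."""
    if category == CAT_GENERIC:
        return frozenset(GROUPS)
    if category.startswith(f"{CAT_SEX}:"):
        sex = category.split(":", 1)[1]
        return frozenset(group_token(sex, s) for s in STRAINS)
    if category.startswith(f"{CAT_STRAIN}:"):
        strain = category.split(":", 1)[1]
        return frozenset(group_token(sex, strain) for sex in SEXES)
    if category.startswith(f"{CAT_EXCLUSIVE}:"):
        return frozenset([category.split(":", 1)[1]])
    if category == CAT_UNCATEGORIZED:
        # two strains of one sex: matches no category by construction
        sex = SEXES[variant % 2]
        s1 = STRAINS[variant % 3]
        s2 = STRAINS[(variant + 1) % 3]
        return frozenset([group_token(sex, s1), group_token(sex, s2)])
    raise ValueError(f"unknown planted category {category!r}")


def _nb_draw(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """NB draws parameterized by mean and size (dispersion)."""
    mean = np.asarray(mean, dtype=float)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=mean.shape).astype(float)


def simulate_compound_table(
    design: CompoundDesign | None = None,
) -> tuple[CompoundTable, pd.DataFrame]:
    """Draw a seeded abundance table with planted categories.

    A compound planted as present in a group has per-sample abundance
    1 + NB(mean x bias, dispersion), thinned by ``detection_dropout``;
    absent groups are exact zeros unless ``contamination_rate`` > 0.
    Returns the table plus a ground-truth frame (compound_id, category,
    pattern of truly-present groups).
    """
    design = design or CompoundDesign()
    rng = np.random.default_rng(design.seed)
    n_per = design.n_samples_per_group

    sample_rows = []
    for g in GROUPS:
        sex, strain = g.split("-", 1)
        for i in range(n_per):
            sample_rows.append(
                {
                    "sample_id": f"{g}-{i + 1:02d}",
                    "sex": sex,
                    "strain": strain,
                    "individual": i + 1,
                }
            )
    sample_meta = pd.DataFrame(sample_rows).set_index("sample_id")

    compounds: list[dict] = []
    for category, count in design.category_counts.items():
        _category_pattern(category, 0)  # validate early
        for v in range(count):
            compounds.append({"category": category, "variant": v})

    n_compounds = len(compounds)
    abundance = np.zeros((n_compounds, len(sample_meta)))
    comp_ids, truth_rows, meta_rows = [], [], []
    col_group = sample_meta.index.str.rsplit("-", n=1).str[0]

    for ci, comp in enumerate(compounds):
        comp_id = f"cmp_{ci:04d}"
        comp_ids.append(comp_id)
        pattern = _category_pattern(comp["category"], comp["variant"])
        base_mean = design.nb_mean * 10 ** rng.normal(0.0, design.mean_spread_log10)
        comp_class = "VOC" if rng.random() < design.voc_fraction else "protein"
        for g in GROUPS:
            cols = np.flatnonzero(col_group == g)
            if g in pattern:
                mean = base_mean * design.concentration_bias.get(g, 1.0)
                vals = 1.0 + _nb_draw(rng, np.full(cols.size, mean), design.nb_dispersion)
                if design.detection_dropout > 0:
                    vals[rng.random(cols.size) < design.detection_dropout] = 0.0
                abundance[ci, cols] = vals
            elif design.contamination_rate > 0:
                hit = rng.random(cols.size) < design.contamination_rate
                vals = np.where(hit, 1.0 + _nb_draw(
                    rng, np.full(cols.size, 0.05 * base_mean), design.nb_dispersion
                ), 0.0)
                abundance[ci, cols] = vals
        meta_rows.append(
            {"compound_id": comp_id, "class": comp_class, "family": design.family}
        )
        truth_rows.append(
            {
                "compound_id": comp_id,
                "category": comp["category"],
                "pattern": ";".join(sorted(pattern)),
            }
        )

    table = CompoundTable(
        abundance=pd.DataFrame(
            abundance, index=comp_ids, columns=sample_meta.index
        ),
        compound_meta=pd.DataFrame(meta_rows).set_index("compound_id"),
        sample_meta=sample_meta,
    )
    truth = pd.DataFrame(truth_rows).set_index("compound_id")
    return table, truth


def lipocalin_design(seed: int = 0, detection_dropout: float = 0.1) -> CompoundDesign:
    """A 27-compound lipocalin-like design: 3 generic carrier proteins plus
    4 combination-exclusive markers per sex/strain group (24), mirroring the
    scale of the urinary lipocalin repertoire."""
    counts = {CAT_GENERIC: 3, **{f"{CAT_EXCLUSIVE}:{g}": 4 for g in GROUPS}}
    return CompoundDesign(
        category_counts=counts,
        detection_dropout=detection_dropout,
        voc_fraction=0.0,
        family="lipocalin",
        seed=seed,
    )
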