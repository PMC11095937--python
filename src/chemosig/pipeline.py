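"""End-to-end pipeline: simulate -> detect/classify -> profile -> report.

A :class:`RunConfig` captures every semantic knob (seed, detection criteria,
presence thresholds, histogram bin width).  :func:`run_pipeline` executes the
stages, writes all intermediate tables as TSV/JSON under the output
directory, and finishes with a manifest (package version, seed, config hash)
so that a run is reproducible byte-for-byte given the same seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import chem, io, stats, synth
from .model import CompoundProfileModel, VSNResponseModel
from .protocol import StimulusProtocol, make_protocol
from .traces import DetectionCriteria

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Semantic configuration of an end-to-end run."""

    seed: int = 0
    protocol_path: str | None = None  # None -> default alternating protocol
    # detection criteria
    baseline_window_s: float = 20.0
    response_window_s: float = 15.0
    sd_multiplier: float = 2.0
    sustain_s: float = 3.0
    k_required: bool = True
    require_both_presentations: bool = False
    # synth population
    n_neurons: int = 500
    noise_sd: float = 0.02
    # chem thresholds
    k_present: int = 3
    k_enriched: int = 6
    k_unique: int = 4
    detection_threshold: float = 0.0
    n_samples_per_group: int = 10
    detection_dropout: float = 0.1
    male_protein_bias: float = 1.5
    # reporting
    bin_width: float = 0.05
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()

    def criteria(self) -> DetectionCriteria:
        return DetectionCriteria(
            baseline_window_s=self.baseline_window_s,
            response_window_s=self.response_window_s,
            sd_multiplier=self.sd_multiplier,
            sustain_s=self.sustain_s,
            k_required=self.k_required,
            require_both_presentations=self.require_both_presentations,
        )


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonable) + "\n")


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        v = float(x)
        return None if np.isnan(v) else v
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON-serializable: {type(x)}")


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Run the full synthetic study and write all outputs under ``out_dir``.

    Returns the run report (also written to report.json).  Any stage failure
    is re-raised as :class:`StageError` naming the stage.
    """
    if config.protocol_path is not None and not Path(config.protocol_path).exists():
        raise FileNotFoundError(f"protocol file not found: {config.protocol_path}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    report: dict = {"seed": config.seed}

    # -- stage: simulate ------------------------------------------------
    try:
        if config.protocol_path is not None:
            protocol = StimulusProtocol.from_json(config.protocol_path)
        else:
            protocol = make_protocol()
        protocol.to_json(out / "protocol.json")

        pop_spec = synth.PopulationSpec(
            n_neurons=config.n_neurons,
            noise_sd=config.noise_sd,
            seed=config.seed,
        )
        traces, trace_truth = synth.simulate_traces(protocol, pop_spec)
        io.write_traces(traces, out / "traces.tsv")
        io.write_trace_truth(trace_truth, out / "traces_truth.json")

        design = synth.CompoundDesign(
            n_samples_per_group=config.n_samples_per_group,
            detection_dropout=config.detection_dropout,
            seed=config.seed + 1,
        )
        table, chem_truth = synth.simulate_compound_table(design)
        if config.male_protein_bias != 1.0:
            # emulate higher protein concentration in male urine
            proteins = table.compound_meta.index[
                table.compound_meta["class"] == "protein"
            ]
            male_cols = table.sample_meta.index[
                table.sample_meta["sex"] == "male"
            ]
            table.abundance.loc[proteins, male_cols] *= config.male_protein_bias
        io.write_compound_table(
            table, out / "compounds.tsv", out / "compound_meta.tsv",
            out / "sample_meta.tsv",
        )
        io.write_truth(chem_truth, out / "compounds_truth.tsv")
    except Exception as e:  # noqa: BLE001 - stage tagging
        raise StageError("simulate", e) from e

    # -- stage: classify -------------------------------------------------
    try:
        vsn = VSNResponseModel(traces, protocol, config.criteria()).fit()
        vsn.events.to_csv(out / "events.tsv", sep="\t", index=False,
                          float_format="%.10g")
        vsn.classifications.to_csv(out / "classification.tsv", sep="\t",
                                   index=False, float_format="%.10g")
        pop = vsn.population_summary()
        _write_json(pop, out / "population_summary.json")
        report["population"] = pop
    except Exception as e:  # noqa: BLE001
        raise StageError("classify", e) from e

    # -- stage: profile ---------------------------------------------------
    try:
        profile = CompoundProfileModel(
            table,
            k_present=config.k_present,
            k_enriched=config.k_enriched,
            k_unique=config.k_unique,
            detection_threshold=config.detection_threshold,
        ).fit(mode="sixway")
        profile.presence.to_csv(out / "presence.tsv", sep="\t", index=False)
        profile.categories.to_csv(out / "categories.tsv", sep="\t")
        profile.intersections.to_csv(out / "intersections.tsv", sep="\t",
                                     index=False)
        report["chem_categories"] = {
            k: int(v) for k, v in profile.category_counts().items()
        }
    except Exception as e:  # noqa: BLE001
        raise StageError("profile", e) from e

    # -- stage: report ----------------------------------------------------
    try:
        hist = vsn.ri_histogram(bin_width=config.bin_width)
        fit = None
        if int((hist.counts > 0).sum()) >= 5:
            fit = stats.fit_gaussians(hist, n_components=1)
        report["ri_histogram"] = {
            "bin_edges": hist.bin_edges.tolist(),
            "counts": hist.counts.tolist(),
            "n_total": hist.n_total,
        }
        if fit is not None:
            report["ri_gaussian_fit"] = {
                "components": [
                    {"weight": c.weight, "mu": c.mu, "sigma": c.sigma}
                    for c in fit.components
                ],
                "rss": fit.rss,
            }
        ci = profile.concentration_indices(
            chem.group_token("male", "C57BL/6"),
            chem.group_token("female", "C57BL/6"),
        )
        report["ci_male_vs_female_C57BL6"] = {
            "n": int(len(ci)),
            "median": float(ci["ci"].median()) if len(ci) else None,
        }
        _write_json(report, out / "report.json")
    except Exception as e:  # noqa: BLE001
        raise StageError("report", e) from e

    # -- manifest ---------------------------------------------------------
    from . import __version__

    manifest = {
        "package": "chemosig",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "outputs": sorted(
            p.name for p in out.iterdir() if p.is_file() and p.name != "manifest.json"
        ),
    }
    _write_json(manifest, out / "manifest.json")
    return report
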