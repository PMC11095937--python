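"""Model / Results interfaces over the analysis pipeline.

Two model classes wrap the functional core the way statistical modelling
packages present estimators: a model object is built from data, ``fit()``
runs the analysis, and the returned results object carries the per-unit
calls, the derived indices and a ``summary()`` table.

* :class:`VSNResponseModel` -- trace set + stimulus protocol -> response
  events, neuron classes, RI / ReI indices, population summary.
* :class:`CompoundProfileModel` -- compound table -> presence calls, six-way
  or pairwise categories, intersection counts, concentration indices.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import chem, stats
from .chem import CompoundTable
from .protocol import StimulusProtocol
from .traces import (
    DetectionCriteria,
    TraceSet,
    classify_neurons,
    detect_responses,
    summarize_population,
)


class VSNResponseModel:
    """Classify a VSN population's responses to a paired-stimulus protocol."""

    def __init__(
        self,
        traces: TraceSet,
        protocol: StimulusProtocol,
        criteria: DetectionCriteria | None = None,
    ):
        self.traces = traces
        self.protocol = protocol
        self.criteria = criteria or DetectionCriteria()

    @classmethod
    def from_files(
        cls,
        traces_path: str | Path,
        protocol_path: str | Path,
        criteria: DetectionCriteria | None = None,
    ) -> "VSNResponseModel":
        from .io import read_traces

        return cls(
            read_traces(traces_path),
            StimulusProtocol.from_json(protocol_path),
            criteria,
        )

    def fit(self) -> "VSNResponseResults":
        events = detect_responses(self.traces, self.protocol, self.criteria)
        classifications = classify_neurons(
            events, self.criteria, stim_labels=self.protocol.stimulus_labels
        )
        return VSNResponseResults(
            model=self, events=events, classifications=classifications
        )


@dataclass
class VSNResponseResults:
    """Per-event detections, per-neuron classes, and population summaries."""

    model: VSNResponseModel
    events: pd.DataFrame
    classifications: pd.DataFrame

    def population_summary(self, experiment_ids=None) -> dict:
        return summarize_population(self.classifications, experiment_ids)

    def ri_values(self, neuron_class: str | None = "generalist") -> np.ndarray:
        df = self.classifications
        if neuron_class is not None:
            df = df[df["neuron_class"] == neuron_class]
        return df["ri"].dropna().to_numpy()

    def rei_values(self, kind: str = "amp") -> np.ndarray:
        cols = [c for c in self.classifications.columns if c.startswith(f"rei_{kind}_")]
        vals = self.classifications[cols].to_numpy().ravel()
        return vals[~np.isnan(vals)]

    def ri_histogram(self, bin_width: float = 0.05) -> stats.IndexHistogram:
        return stats.build_histogram(self.ri_values(), bin_width, source="RI")

    def summary(self) -> str:
        s = self.population_summary()
        lines = [
            "VSN response classification",
            "===========================",
            f"ROIs analysed:        {s['n_rois']}",
            f"K+-sensitive:         {s['n_k_sensitive']}",
            f"urine-sensitive:      {s['n_urine_sensitive']}",
            "",
            f"{'class':<16}{'n':>8}{'% urine-sens.':>16}",
        ]
        for cls_name, n in sorted(s["counts"].items()):
            pct = s["pct_of_urine_sensitive"].get(cls_name)
            lines.append(
                f"{cls_name:<16}{n:>8}{(f'{pct:.1f}' if pct is not None else '-'):>16}"
            )
        return "\n".join(lines)

    def plot_trace(self, roi_id: str, ax=None):
        from .plotting import plot_trace

        return plot_trace(self.model.traces, self.model.protocol, roi_id, ax=ax)


class CompoundProfileModel:
    """Profile a sample x compound table into molecular categories."""

    def __init__(
        self,
        table: CompoundTable,
        k_present: int = 3,
        k_enriched: int = 6,
        k_unique: int = 4,
        detection_threshold: float = 0.0,
    ):
        self.table = table
        self.k_present = k_present
        self.k_enriched = k_enriched
        self.k_unique = k_unique
        self.detection_threshold = detection_threshold

    @classmethod
    def from_files(
        cls, table_path, compound_meta_path, sample_meta_path, **kwargs
    ) -> "CompoundProfileModel":
        from .io import read_compound_table

        return cls(
            read_compound_table(table_path, compound_meta_path, sample_meta_path),
            **kwargs,
        )

    def presence_calls(self) -> pd.DataFrame:
        return chem.call_presence(
            self.table, self.k_present, self.k_enriched, self.detection_threshold
        )

    def fit(
        self, mode: str = "sixway", groups: tuple[str, str] | None = None
    ) -> "CompoundProfileResults":
        calls = self.presence_calls()
        if mode == "sixway":
            categories = chem.six_way_categorize(calls)
            intersections, group_totals = chem.intersection_counts(calls)
            pairwise = None
        elif mode == "pairwise":
            if groups is None or len(groups) != 2:
                raise ValueError("pairwise mode needs groups=(group_1, group_2)")
            pairwise = chem.pairwise_categorize(calls, *groups)
            categories = pairwise.to_frame()
            intersections, group_totals = None, None
        else:
            raise ValueError(f"unknown mode {mode!r}")
        return CompoundProfileResults(
            model=self,
            mode=mode,
            groups=groups,
            presence=calls,
            categories=categories,
            intersections=intersections,
            group_totals=group_totals,
        )


@dataclass
class CompoundProfileResults:
    """Presence calls and category assignments for a compound table."""

    model: CompoundProfileModel
    mode: str
    groups: tuple[str, str] | None
    presence: pd.DataFrame
    categories: pd.DataFrame
    intersections: pd.DataFrame | None = None
    group_totals: pd.Series | None = None

    def category_counts(self) -> pd.Series:
        return self.categories["category"].value_counts()

    def concentration_indices(
        self, group_1: str, group_2: str, compound_class: str | None = None
    ) -> pd.DataFrame:
        """CIs for the generic compounds of a binary comparison."""
        calls = self.presence
        pairwise = chem.pairwise_categorize(calls, group_1, group_2)
        generics = pairwise.index[pairwise == chem.CAT_GENERIC]
        if compound_class is not None:
            meta = self.model.table.compound_meta
            generics = [
                c for c in generics if meta.loc[c, "class"] == compound_class
            ]
        return chem.concentration_index(
            self.model.table, group_1, group_2, compounds=list(generics)
        )

    def summary(self) -> str:
        counts = self.category_counts()
        total = int(counts.sum())
        lines = [
            "Compound profiling" + (f" ({self.mode})" if self.mode else ""),
            "==================",
            f"compounds: {total}",
            "",
            f"{'category':<28}{'n':>6}{'%':>8}",
        ]
        for cat, n in counts.items():
            lines.append(
                f"{cat:<28}{n:>6}{stats.round_half_up(100 * n / total):>8.1f}"
            )
        return "\n".join(lines)
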