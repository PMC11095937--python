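"""Presence calls, category assignment and concentration indices for
sample x compound abundance tables.

Samples belong to one of six sex/strain groups (male/female x C57BL/6,
BALB/c, wild; 10 individuals per group in the reference design).  A compound
is "present" in a group when detected in >= 3 of 10 individual samples and
"enriched" when detected in >= 6 of 10.  Pairwise comparisons categorize
compounds as generic (present in both groups) or specific (present in one);
the six-way scheme over enriched calls yields generic, sex-specific,
strain-specific, combination-exclusive, or uncategorized compounds.
Concentration indices CI = (mean1 - mean2) / (mean1 + mean2) quantify
group-wise concentration bias of shared compounds, with group means taken
over *all* samples of a group (non-detections counted as zeros).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd

logger = logging.getLogger(__name__)

SEXES = ("male", "female")
STRAINS = ("C57BL/6", "BALB/c", "wild")


def group_token(sex: str, strain: str) -> str:
    return f"{sex}-{strain}"


#: Canonical group order: males first, strains in fixed order.
GROUPS = tuple(group_token(sex, strain) for sex in SEXES for strain in STRAINS)

CAT_GENERIC = "generic"
CAT_SEX = "sex_specific"
CAT_STRAIN = "strain_specific"
CAT_EXCLUSIVE = "exclusive"
CAT_UNCATEGORIZED = "uncategorized"

COMPOUND_CLASSES = ("VOC", "protein")


@dataclass
class CompoundTable:
    """Nonnegative abundance matrix (compounds x samples) with metadata.

    ``compound_meta`` is indexed by compound id with columns ``class``
    (VOC / protein) and optional ``family``; ``sample_meta`` is indexed by
    sample id with columns ``sex``, ``strain`` and ``individual``.
    """

    abundance: pd.DataFrame
    compound_meta: pd.DataFrame
    sample_meta: pd.DataFrame
    allowed_sexes: tuple = SEXES
    allowed_strains: tuple = STRAINS

    def __post_init__(self) -> None:
        if (self.abundance.to_numpy() < 0).any():
            r, c = np.argwhere(self.abundance.to_numpy() < 0)[0]
            raise ValueError(
                f"negative abundance at compound {self.abundance.index[r]!r}, "
                f"sample {self.abundance.columns[c]!r}"
            )
        missing = set(self.abundance.columns) ^ set(self.sample_meta.index)
        if missing:
            raise ValueError(
                f"samples in table and metadata do not match: {sorted(missing)}"
            )
        if not set(self.abundance.index) <= set(self.compound_meta.index):
            extra = sorted(set(self.abundance.index) - set(self.compound_meta.index))
            raise ValueError(f"compounds missing from metadata: {extra}")
        bad_sex = set(self.sample_meta["sex"]) - set(self.allowed_sexes)
        bad_strain = set(self.sample_meta["strain"]) - set(self.allowed_strains)
        if bad_sex or bad_strain:
            raise ValueError(
                f"unknown sex/strain tokens: {sorted(bad_sex | bad_strain)}"
            )
        # align metadata to the table's column order; canonical index names
        self.sample_meta = self.sample_meta.loc[self.abundance.columns]
        self.compound_meta = self.compound_meta.loc[self.abundance.index]
        self.abundance = self.abundance.astype(float)
        self.abundance.index.name = "compound_id"
        self.abundance.columns.name = None
        self.compound_meta.index.name = "compound_id"
        self.sample_meta.index.name = "sample_id"

    @property
    def groups(self) -> pd.Series:
        """Group token per sample, aligned with the abundance columns."""
        return pd.Series(
            [
                group_token(s, t)
                for s, t in zip(self.sample_meta["sex"], self.sample_meta["strain"])
            ],
            index=self.sample_meta.index,
            name="group",
        )

    def subset_compounds(self, compound_ids: Sequence[str]) -> "CompoundTable":
        return replace(
            self,
            abundance=self.abundance.loc[list(compound_ids)],
            compound_meta=self.compound_meta.loc[list(compound_ids)],
        )

    def subset_family(self, family: str) -> "CompoundTable":
        ids = self.compound_meta.index[self.compound_meta["family"] == family]
        if len(ids) == 0:
            raise ValueError(f"no compounds with family {family!r}")
        return self.subset_compounds(ids)


# ---------------------------------------------------------------------------
# presence calls
# ---------------------------------------------------------------------------

def detection_counts(
    table: CompoundTable, detection_threshold: float = 0.0
) -> pd.DataFrame:
    """Per (compound, group) count of samples with abundance > threshold."""
    detected = table.abundance > detection_threshold
    return detected.T.groupby(table.groups).sum().T


def call_presence(
    table: CompoundTable,
    k_present: int = 3,
    k_enriched: int = 6,
    detection_threshold: float = 0.0,
) -> pd.DataFrame:
    """Presence / enrichment calls per (compound, group).

    Thresholds are absolute sample counts (>=3 / >=6 of the reference
    10-per-group design); they apply unchanged to other group sizes.
    Returns a long frame: compound_id, group, n_detected, present, enriched.
    """
    if k_enriched < k_present:
        raise ValueError("k_enriched must be >= k_present")
    sizes = table.groups.value_counts()
    if k_enriched > sizes.max():
        raise ValueError("k_enriched exceeds the largest group size")
    counts = detection_counts(table, detection_threshold)
    long = counts.stack().rename("n_detected").reset_index()
    long.columns = ["compound_id", "group", "n_detected"]
    long["present"] = long["n_detected"] >= k_present
    long["enriched"] = long["n_detected"] >= k_enriched
    return long


def _counts_for(calls: pd.DataFrame) -> pd.DataFrame:
    """Pivot a long presence-call frame back to compounds x groups counts."""
    return calls.pivot(index="compound_id", columns="group", values="n_detected")


# ---------------------------------------------------------------------------
# categorization
# ---------------------------------------------------------------------------

def pairwise_categorize(
    calls: pd.DataFrame, group_1: str, group_2: str
) -> pd.Series:
    """Binary-comparison categories from presence calls.

    generic = present in both groups; ``specific:<group>`` = present in
    exactly one; absent = neither (such compounds are dropped from
    comparison summaries downstream).
    """
    wide = calls.pivot(index="compound_id", columns="group", values="present")
    for g in (group_1, group_2):
        if g not in wide.columns:
            raise ValueError(f"no presence calls for group {g!r}")
    p1 = wide[group_1].astype(bool)
    p2 = wide[group_2].astype(bool)
    out = pd.Series("absent", index=wide.index, name="category", dtype=object)
    out[p1 & p2] = CAT_GENERIC
    out[p1 & ~p2] = f"specific:{group_1}"
    out[~p1 & p2] = f"specific:{group_2}"
    return out


def six_way_categorize(calls: pd.DataFrame) -> pd.DataFrame:
    """Six-group categorization over *enriched* calls.

    Categories (exactly one per compound):

    * ``generic`` -- enriched in all six groups;
    * ``sex_specific:<sex>`` -- enriched in all three groups of one sex and
      in none of the other sex;
    * ``strain_specific:<strain>`` -- enriched in both sexes of one strain
      and in no other group;
    * ``exclusive:<group>`` -- enriched in exactly one group;
    * ``uncategorized`` -- any other pattern (including enriched nowhere).

    Returns a frame indexed by compound id with columns ``category`` and
    ``pattern`` (the 6-bit presence string in canonical group order).
    """
    wide = calls.pivot(index="compound_id", columns="group", values="enriched")
    missing = set(GROUPS) - set(wide.columns)
    if missing:
        raise ValueError(f"missing enriched calls for groups: {sorted(missing)}")
    wide = wide[list(GROUPS)].astype(bool)

    sex_patterns = {
        sex: frozenset(group_token(sex, s) for s in STRAINS) for sex in SEXES
    }
    strain_patterns = {
        strain: frozenset(group_token(x, strain) for x in SEXES)
        for strain in STRAINS
    }

    rows = []
    for comp_id, flags in wide.iterrows():
        on = frozenset(g for g in GROUPS if flags[g])
        if len(on) == 6:
            cat = CAT_GENERIC
        elif on in sex_patterns.values():
            sex = next(s for s, p in sex_patterns.items() if p == on)
            cat = f"{CAT_SEX}:{sex}"
        elif on in strain_patterns.values():
            strain = next(s for s, p in strain_patterns.items() if p == on)
            cat = f"{CAT_STRAIN}:{strain}"
        elif len(on) == 1:
            cat = f"{CAT_EXCLUSIVE}:{next(iter(on))}"
        else:
            cat = CAT_UNCATEGORIZED
        rows.append(
            {
                "compound_id": comp_id,
                "category": cat,
                "pattern": "".join("1" if flags[g] else "0" for g in GROUPS),
            }
        )
    return pd.DataFrame(rows).set_index("compound_id")


def intersection_counts(calls: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """UpSet-style bookkeeping over enriched calls.

    Returns (intersections, group_totals): one count per distinct nonzero
    6-bit pattern sorted by size descending (ties by pattern string), plus
    per-group enriched totals.
    """
    wide = calls.pivot(index="compound_id", columns="group", values="enriched")
    missing = set(GROUPS) - set(wide.columns)
    if missing:
        raise ValueError(f"missing enriched calls for groups: {sorted(missing)}")
    wide = wide[list(GROUPS)].astype(bool)
    patterns = wide.apply(
        lambda row: "".join("1" if v else "0" for v in row), axis=1
    )
    counts = patterns[patterns != "0" * len(GROUPS)].value_counts()
    inter = counts.rename("count").rename_axis("pattern").reset_index()
    inter = inter.sort_values(
        ["count", "pattern"], ascending=[False, True]
    ).reset_index(drop=True)
    totals = wide.sum(axis=0)
    totals.name = "n_enriched"
    return inter, totals


def unique_compounds(
    table: CompoundTable,
    group_1: str,
    group_2: str,
    k_unique: int = 4,
    detection_threshold: float = 0.0,
) -> dict[str, list[str]]:
    """Group-specific ("unique") compounds in a binary comparison: detected
    in >= k_unique samples of one group and in zero samples of the other."""
    counts = detection_counts(table, detection_threshold)
    out: dict[str, list[str]] = {}
    for a, b in ((group_1, group_2), (group_2, group_1)):
        mask = (counts[a] >= k_unique) & (counts[b] == 0)
        out[a] = list(counts.index[mask])
    return out


def reduce_rows(
    table: CompoundTable,
    group_1: str,
    group_2: str,
    detection_threshold: float = 0.0,
) -> CompoundTable:
    """Drop compounds detected in <= 3 individuals in *both* groups; a row is
    retained as soon as one group has >= 4 detections."""
    counts = detection_counts(table, detection_threshold)
    keep = (counts[group_1] >= 4) | (counts[group_2] >= 4)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("reduce_rows: dropped %d of %d compounds", dropped, len(keep))
    return table.subset_compounds(counts.index[keep])


# ---------------------------------------------------------------------------
# concentration indices
# ---------------------------------------------------------------------------

def concentration_index(
    table: CompoundTable,
    group_1: str,
    group_2: str,
    compounds: Sequence[str] | None = None,
) -> pd.DataFrame:
    """CI = (mean1 - mean2) / (mean1 + mean2) per compound.

    Group means are taken over all samples of the group, counting
    non-detections as zeros.  Compounds with both means zero are excluded
    (logged), so every returned CI lies in [-1, 1].
    """
    groups = table.groups
    sub = table.abundance if compounds is None else table.abundance.loc[list(compounds)]
    m1 = sub.loc[:, groups[groups == group_1].index].mean(axis=1)
    m2 = sub.loc[:, groups[groups == group_2].index].mean(axis=1)
    denom = m1 + m2
    defined = denom > 0
    if (~defined).any():
        logger.info(
            "concentration_index: excluded %d compounds with zero means in "
            "both groups",
            int((~defined).sum()),
        )
    out = pd.DataFrame(
        {
            "mean_conc_1": m1[defined],
            "mean_conc_2": m2[defined],
            "ci": (m1[defined] - m2[defined]) / denom[defined],
        }
    )
    out.index.name = "compound_id"
    return out


# ---------------------------------------------------------------------------
# normalization and clustering
# ---------------------------------------------------------------------------

def quantile_normalize(table: CompoundTable) -> CompoundTable:
    """Classical quantile normalization across samples (columns).

    Each column's sorted values are replaced by the across-column mean of the
    values at the same rank; ties receive the mean of their rank positions'
    reference values, so every column ends with the identical value multiset
    (up to ties).  All-zero samples are left untouched (logged).
    """
    ab = table.abundance
    nonzero = ab.columns[(ab != 0).any(axis=0)]
    if len(nonzero) < 2:
        raise ValueError("quantile normalization needs >= 2 non-empty samples")
    skipped = set(ab.columns) - set(nonzero)
    if skipped:
        logger.warning(
            "quantile_normalize: leaving all-zero samples unchanged: %s",
            sorted(skipped),
        )
    sub = ab[nonzero].to_numpy(dtype=float)
    reference = np.sort(sub, axis=0).mean(axis=1)

    normalized = np.empty_like(sub)
    for j in range(sub.shape[1]):
        col = sub[:, j]
        order = np.argsort(col, kind="mergesort")
        ranked = np.empty_like(reference)
        ranked[order] = reference
        # ties receive the mean of their rank positions' reference values
        tied = pd.Series(ranked).groupby(col, sort=False).transform("mean")
        normalized[:, j] = tied.to_numpy()

    out = ab.copy()
    out[nonzero] = normalized
    return replace(table, abundance=out)


@dataclass
class ClusterResult:
    """Agglomerative clustering of samples with group-agreement scoring."""

    linkage_matrix: np.ndarray
    labels: pd.Series
    k: int
    agreement: float
    n_agreeing: int


def cluster_samples(
    table: CompoundTable,
    family: str | None = None,
    k: int = 6,
    metric: str = "euclidean",
    linkage: str = "average",
    log_transform: bool = True,
    normalize: bool = True,
) -> ClusterResult:
    """Hierarchically cluster samples on (log10(x+1), quantile-normalized)
    abundance profiles and score cluster-group agreement.

    Agreement is the fraction of samples whose flat cluster's majority group
    matches their own group, at a cut into ``k`` clusters.
    """
    sub = table.subset_family(family) if family else table
    if normalize:
        sub = quantile_normalize(sub)
    data = sub.abundance.to_numpy().T  # samples x compounds
    if log_transform:
        data = np.log10(data + 1.0)
    if np.allclose(data, data[0]):
        raise ValueError("constant profiles: pairwise distances are degenerate")
    dist = ssd.pdist(data, metric=metric)
    z = sch.linkage(dist, method=linkage)
    flat = sch.fcluster(z, t=k, criterion="maxclust")
    labels = pd.Series(flat, index=sub.abundance.columns, name="cluster")

    groups = sub.groups
    agree = 0
    for cluster_id in np.unique(flat):
        members = labels.index[labels == cluster_id]
        majority = groups.loc[members].mode().iloc[0]
        agree += int((groups.loc[members] == majority).sum())
    n = len(labels)
    return ClusterResult(
        linkage_matrix=z,
        labels=labels,
        k=k,
        agreement=agree / n,
        n_agreeing=agree,
    )
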