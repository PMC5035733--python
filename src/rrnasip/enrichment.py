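"""Taxon-specific read enrichment factors from heavy/light SIP fractions.

The enrichment factor (EF) of a taxon contrasts its heavy:light relative-
abundance ratio in a 13C-substrate gradient with the same ratio in the
paired 12C-control gradient:

    EF = c13_heavy / c13_light - c12_heavy / c12_light

where each term is the taxon's relative read abundance in the sequenced
heavy or light fraction of the respective gradient. An EF near zero means
the taxon bands identically whether or not the substrate carried label;
a large positive EF means its rRNA moved into the heavy fraction only when
13C was available, i.e. the taxon assimilated substrate-derived carbon.

Labeling rules applied here:

* EFs are computed for taxa whose relative abundance in a heavy 13C
  fraction exceeds an abundance threshold (default 2%, strict) in at least
  one treatment x timepoint; protist taxa are exempt from this filter.
* A taxon is called 13C-labeled if any of its EFs exceeds the EF threshold
  (default 0.5, strict) in at least one treatment or timepoint.
* For log-scale display, records with non-positive EF belonging to a taxon
  labeled elsewhere are floored at log10 = -1.5.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from rrnasip.simulate import GradientTable

__all__ = [
    "relative_abundance",
    "compute_ef",
    "enrichment_table",
    "abundance_filter",
    "call_labeled",
    "display_value",
    "summarize_labels",
    "analyze_gradients",
]

DISPLAY_FLOOR = -1.5


class EmptyFractionError(ValueError):
    """A sequenced fraction contains no reads at all."""


def relative_abundance(counts, pseudocount: float = 1.0) -> np.ndarray:
    """Per-taxon read proportions within one fraction.

    A pseudocount added to every taxon before normalization keeps
    heavy:light ratios finite for taxa unobserved in one fraction
    (``pseudocount=0`` disables this, and downstream ratio computation will
    then raise on zero denominators).
    """
    c = np.asarray(counts, dtype=float)
    if c.ndim != 1:
        raise ValueError("counts must be one-dimensional")
    if np.any(c < 0):
        raise ValueError("negative read counts")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    if c.sum() == 0:
        raise EmptyFractionError("fraction contains zero reads for every taxon")
    c = c + pseudocount
    return c / c.sum()


def compute_ef(c13_heavy, c13_light, c12_heavy, c12_light):
    """Enrichment factor: difference of heavy:light abundance ratios.

    Accepts scalars or aligned arrays of relative abundances in [0, 1].
    """
    h13 = np.asarray(c13_heavy, dtype=float)
    l13 = np.asarray(c13_light, dtype=float)
    h12 = np.asarray(c12_heavy, dtype=float)
    l12 = np.asarray(c12_light, dtype=float)
    for name, v in (("c13", l13), ("c12", l12)):
        if np.any(v == 0):
            raise ZeroDivisionError(
                f"zero light-fraction abundance in the {name} gradient; "
                "enable a pseudocount or drop the taxon"
            )
    ef = h13 / l13 - h12 / l12
    return float(ef) if ef.ndim == 0 else ef


def enrichment_table(
    c13: GradientTable,
    c12: GradientTable,
    heavy_fraction: int = 3,
    light_fraction: int = 8,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-taxon abundances and EF for one paired 13C/12C gradient.

    Taxa are taken as the union of both tables; a taxon missing from one
    table is treated as zero-count there (then pseudocounted). Returns a
    frame indexed by taxon with the four relative abundances, the EF, and
    ``heavy_abundance`` (the taxon's share of heavy 13C-fraction reads).
    """
    if (c13.substrate, c13.timepoint) != (c12.substrate, c12.timepoint):
        raise ValueError(
            "13C and 12C gradients must share substrate and timepoint "
            f"(got {c13.substrate}/{c13.timepoint} vs {c12.substrate}/{c12.timepoint})"
        )
    taxa = c13.counts.index.union(c12.counts.index, sort=False)
    cols = {}
    for tag, table in (("c13", c13), ("c12", c12)):
        for role, fraction in (("heavy", heavy_fraction), ("light", light_fraction)):
            counts = table.fraction_counts(fraction).reindex(taxa, fill_value=0)
            try:
                cols[f"{tag}_{role}"] = relative_abundance(counts.to_numpy(), pseudocount)
            except EmptyFractionError as exc:
                raise EmptyFractionError(
                    f"{tag} fraction {fraction} of {table.substrate}/{table.timepoint}: {exc}"
                ) from exc
    out = pd.DataFrame(cols, index=pd.Index(taxa, name="taxon"))
    out["ef"] = compute_ef(
        out["c13_heavy"].to_numpy(),
        out["c13_light"].to_numpy(),
        out["c12_heavy"].to_numpy(),
        out["c12_light"].to_numpy(),
    )
    out["heavy_abundance"] = out["c13_heavy"]
    return out


def abundance_filter(
    heavy_abundances: pd.DataFrame | Mapping[str, Iterable[float]],
    threshold: float = 0.02,
    groups: Mapping[str, str] | None = None,
    exempt_groups: frozenset[str] | set[str] = frozenset({"protist"}),
) -> list[str]:
    """Taxa retained for EF calculation.

    A taxon is retained iff its relative abundance in the heavy 13C fraction
    exceeds ``threshold`` (strictly) in at least one treatment x timepoint,
    or its group is exempt (protists by default, which are analyzed
    regardless of abundance).

    ``heavy_abundances`` maps taxon -> heavy-fraction abundances across all
    cells (a DataFrame with taxa as index also works).
    """
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must be in [0,1]")
    if isinstance(heavy_abundances, pd.DataFrame):
        items = ((t, row.to_numpy()) for t, row in heavy_abundances.iterrows())
    else:
        items = ((t, np.asarray(list(v), dtype=float)) for t, v in heavy_abundances.items())
    groups = groups or {}
    retained = []
    for taxon, vals in items:
        if groups.get(taxon) in exempt_groups or np.nanmax(vals) > threshold:
            retained.append(taxon)
    return retained


def call_labeled(efs: Sequence[float], threshold: float = 0.5) -> bool:
    """True iff any EF strictly exceeds the threshold in any treatment/timepoint."""
    efs = np.asarray(list(efs), dtype=float)
    if efs.size == 0:
        raise ValueError("call_labeled requires at least one EF value")
    return bool(np.any(efs > threshold))


def display_value(ef: float, labeled_elsewhere: bool = True) -> float:
    """Log10 display value for a labeled taxon's EF, floored at -1.5.

    Negative or zero read enrichment for a taxon that is labeled in another
    treatment or timepoint is mapped to the floor so it remains visible on
    a log-scale panel.
    """
    if ef > 0:
        return max(float(np.log10(ef)), DISPLAY_FLOOR)
    if labeled_elsewhere:
        return DISPLAY_FLOOR
    raise ValueError("display_value is defined only for taxa passing the labeling call")


def analyze_gradients(
    pairs: Iterable[tuple[GradientTable, GradientTable]],
    groups: Mapping[str, str] | None = None,
    heavy_fraction: int = 3,
    light_fraction: int = 8,
    abundance_threshold: float = 0.02,
    ef_threshold: float = 0.5,
    pseudocount: float = 1.0,
    exempt_groups: frozenset[str] | set[str] = frozenset({"protist"}),
) -> pd.DataFrame:
    """Full EF analysis over all paired gradients.

    Normalization happens over all reads in each sequenced fraction first;
    the abundance filter is applied second. Returns one row per retained
    taxon x substrate x timepoint with the four abundances, EF, labeling
    call (per taxon, across all its cells) and display value (NaN for
    unlabeled taxa).
    """
    groups = dict(groups or {})
    frames = []
    for c13, c12 in pairs:
        tab = enrichment_table(c13, c12, heavy_fraction, light_fraction, pseudocount)
        tab = tab.reset_index()
        tab.insert(1, "substrate", c13.substrate)
        tab.insert(2, "timepoint", c13.timepoint)
        frames.append(tab)
    if not frames:
        raise ValueError("no gradient pairs supplied")
    records = pd.concat(frames, ignore_index=True)
    records["group"] = records["taxon"].map(lambda t: groups.get(t, "bacteria"))

    heavy_wide = records.pivot_table(
        index="taxon", columns=["substrate", "timepoint"], values="heavy_abundance"
    )
    keep = abundance_filter(
        heavy_wide,
        threshold=abundance_threshold,
        groups={t: groups.get(t, "bacteria") for t in heavy_wide.index},
        exempt_groups=exempt_groups,
    )
    records = records[records["taxon"].isin(keep)].copy()

    labeled_by_taxon = records.groupby("taxon")["ef"].apply(
        lambda efs: call_labeled(efs, ef_threshold)
    )
    records["labeled"] = records["taxon"].map(labeled_by_taxon)
    records["display_value"] = [
        display_value(ef, labeled_elsewhere=True) if lab else np.nan
        for ef, lab in zip(records["ef"], records["labeled"])
    ]
    return records.reset_index(drop=True)


def summarize_labels(
    records: pd.DataFrame,
    ef_threshold: float = 0.5,
    strong_abundance: float = 0.10,
) -> pd.DataFrame:
    """Labeled-taxa overview matrix.

    Rows are labeled taxa (ordered by group, then taxon), columns are
    (substrate, timepoint) cells. Marks: ``"+"`` where the taxon's EF
    exceeds the threshold in that cell, ``"++"`` where in addition its
    heavy-fraction abundance is at least ``strong_abundance`` (the most
    markedly labeled cells), ``""`` otherwise. Taxa labeled nowhere are
    excluded. Raises if any taxon is missing a substrate x timepoint cell.
    """
    required = {"taxon", "group", "substrate", "timepoint", "ef", "heavy_abundance", "labeled"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns: {sorted(missing)}")
    labeled = records[records["labeled"]].copy()
    if labeled.empty:
        return pd.DataFrame()
    cells = records[["substrate", "timepoint"]].drop_duplicates()
    expected = len(cells)
    counts = labeled.groupby("taxon").size()
    incomplete = counts[counts != expected]
    if len(incomplete):
        raise ValueError(
            f"incomplete records for taxa {list(incomplete.index)}: "
            f"expected {expected} substrate x timepoint cells"
        )

    def mark(row) -> str:
        if row["ef"] > ef_threshold:
            return "++" if row["heavy_abundance"] >= strong_abundance else "+"
        return ""

    labeled["mark"] = labeled.apply(mark, axis=1)
    matrix = labeled.pivot_table(
        index=["group", "taxon"],
        columns=["substrate", "timepoint"],
        values="mark",
        aggfunc="first",
    ).fillna("")
    return matrix.sort_index()
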