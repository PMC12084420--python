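"""Per-droplet and per-cell neutral-lipid statistics.

A droplet's neutral-lipid content is quantified by summing the TAG and CE
SRS lipid intensities over its pixels (TAG_LD, CE_LD); its composition is
the CE fraction CE_LD / (CE_LD + TAG_LD).  Droplets in which 20% or more of
the pixels are saturated are excluded from quantification.  Cell-wise means
sum the lipid intensities over all droplet pixels (LD quantifications) or
all cellular pixels (cellular quantifications) and divide by the number of
cells.  SRS and biochemical (thin-layer chromatography, TLC) scales are made
comparable by dividing each table by its own CE mean in an anchor condition.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
from skimage.measure import regionprops

from .segmentation import SegmentationMasks, assign_droplets_to_cells, classify_ne_droplets
from .unmixing import WeightImage

logger = logging.getLogger(__name__)

__all__ = [
    "DropletRecord",
    "CellSummary",
    "droplet_records",
    "records_frame",
    "cell_summaries",
    "summaries_frame",
    "size_ce_histogram",
    "anchor_normalize",
    "compare_groups",
    "compare_ne_vs_cyto",
]


@dataclass
class DropletRecord:
    """One segmented lipid droplet and its lipid content."""

    droplet_id: int
    cell_id: int
    is_ne: bool
    pixel_count: int
    tag_sum: float
    ce_sum: float
    ce_fraction: float
    saturated_fraction: float
    equivalent_radius_um: float


@dataclass
class CellSummary:
    """Per-cell lipid totals and NE-LD composition statistics."""

    cell_id: int
    n_droplets: int
    n_ne_droplets: int
    ld_tag_sum: float
    ld_ce_sum: float
    cell_tag_sum: float
    cell_ce_sum: float
    fraction_ne: float
    ce_in_ne_fraction: float


def _ce_fraction(ce: float, tag: float) -> float:
    total = ce + tag
    return ce / total if total > 0 else float("nan")


def droplet_records(
    wi: WeightImage,
    masks: SegmentationMasks,
    max_saturated_fraction: float = 0.20,
    require_normalized: bool = True,
) -> list[DropletRecord]:
    """Build one :class:`DropletRecord` per quantifiable droplet.

    Droplets with ``max_saturated_fraction`` (default 20%) or more saturated
    pixels are excluded.  Weights must have been normalized to a common
    acquisition setting before quantification when records from different
    acquisitions are pooled; pass ``require_normalized=False`` for
    single-acquisition use.
    """
    if require_normalized and wi.normalized_to is None:
        raise ValueError(
            "weights are not normalized to a target acquisition setting; "
            "normalize first or pass require_normalized=False"
        )
    if wi.W.shape[:2] != masks.droplets.shape:
        raise ValueError("weight image and masks differ in shape")
    tag, ce = wi.tag, wi.ce
    sat = wi.saturation_mask
    ne_flags = classify_ne_droplets(masks.droplets, masks.nuclei)
    cell_of = assign_droplets_to_cells(masks.droplets, masks.cells)
    records = []
    for p in regionprops(masks.droplets):
        rr, cc = p.coords[:, 0], p.coords[:, 1]
        sat_frac = float(sat[rr, cc].mean())
        if sat_frac >= max_saturated_fraction:
            continue
        tag_sum = float(tag[rr, cc].sum())
        ce_sum = float(ce[rr, cc].sum())
        records.append(
            DropletRecord(
                droplet_id=int(p.label),
                cell_id=cell_of.get(p.label, 0),
                is_ne=ne_flags.get(p.label, False),
                pixel_count=int(p.area),
                tag_sum=tag_sum,
                ce_sum=ce_sum,
                ce_fraction=_ce_fraction(ce_sum, tag_sum),
                saturated_fraction=sat_frac,
                equivalent_radius_um=float(
                    np.sqrt(p.area / np.pi) * masks.pixel_size_um
                ),
            )
        )
    return records


def records_frame(records: Iterable[DropletRecord]) -> pd.DataFrame:
    cols = [f.name for f in DropletRecord.__dataclass_fields__.values()]
    return pd.DataFrame([asdict(r) for r in records], columns=cols)


def cell_summaries(
    records: Sequence[DropletRecord],
    wi: WeightImage,
    masks: SegmentationMasks,
) -> list[CellSummary]:
    """Per-cell totals over droplet pixels and over all cellular pixels.

    ``cell_tag_sum`` / ``cell_ce_sum`` integrate the lipid planes over every
    pixel of the cell mask, capturing lipid pools outside droplets (e.g. the
    diffuse membrane CE pool); droplet sums are restricted to droplet
    pixels.  For cells with no droplets the ratio metrics are emitted as
    NaN.
    """
    tag, ce = wi.tag, wi.ce
    by_cell: dict[int, list[DropletRecord]] = {}
    for r in records:
        by_cell.setdefault(r.cell_id, []).append(r)
    summaries = []
    for p in regionprops(masks.cells):
        cell_id = int(p.label)
        rr, cc = p.coords[:, 0], p.coords[:, 1]
        recs = by_cell.get(cell_id, [])
        n = len(recs)
        n_ne = sum(r.is_ne for r in recs)
        ld_tag = sum(r.tag_sum for r in recs)
        ld_ce = sum(r.ce_sum for r in recs)
        ne_ce = sum(r.ce_sum for r in recs if r.is_ne)
        summaries.append(
            CellSummary(
                cell_id=cell_id,
                n_droplets=n,
                n_ne_droplets=n_ne,
                ld_tag_sum=ld_tag,
                ld_ce_sum=ld_ce,
                cell_tag_sum=float(tag[rr, cc].sum()),
                cell_ce_sum=float(ce[rr, cc].sum()),
                fraction_ne=n_ne / n if n else float("nan"),
                ce_in_ne_fraction=ne_ce / ld_ce if ld_ce > 0 else float("nan"),
            )
        )
    return summaries


def summaries_frame(summaries: Iterable[CellSummary]) -> pd.DataFrame:
    cols = [f.name for f in CellSummary.__dataclass_fields__.values()]
    return pd.DataFrame([asdict(s) for s in summaries], columns=cols)


def size_ce_histogram(
    records: Sequence[DropletRecord],
    radius_bin_edges_um: Sequence[float],
    ce_bin_edges: Sequence[float],
) -> pd.DataFrame:
    """2D droplet count table: radius bins x CE-fraction bins.

    Records falling outside the given edges are counted in open-ended
    boundary bins.  The table's total equals the number of records with a
    defined CE fraction.
    """
    r_edges = np.asarray(radius_bin_edges_um, dtype=float)
    c_edges = np.asarray(ce_bin_edges, dtype=float)
    for name, e in (("radius", r_edges), ("ce", c_edges)):
        if e.size < 2 or np.any(np.diff(e) <= 0):
            raise ValueError(f"{name} bin edges must be strictly increasing")
    radii = np.array([r.equivalent_radius_um for r in records])
    fracs = np.array([r.ce_fraction for r in records])
    keep = ~np.isnan(fracs) if fracs.size else np.array([], dtype=bool)
    radii, fracs = radii[keep], fracs[keep]
    # open end bins: clamp into the outermost bins
    r_idx = np.clip(np.searchsorted(r_edges, radii, side="right") - 1, 0, r_edges.size - 2)
    c_idx = np.clip(np.searchsorted(c_edges, fracs, side="right") - 1, 0, c_edges.size - 2)
    counts = np.zeros((r_edges.size - 1, c_edges.size - 1), dtype=int)
    np.add.at(counts, (r_idx, c_idx), 1)

    def _labels(edges):
        return [f"[{a:g},{b:g})" for a, b in zip(edges[:-1], edges[1:])]

    df = pd.DataFrame(counts, index=_labels(r_edges), columns=_labels(c_edges))
    df.index.name = "radius_um"
    df.columns.name = "ce_fraction"
    return df


def anchor_normalize(
    srs_by_condition: Mapping[str, float] | pd.Series,
    tlc_by_condition: Mapping[str, float] | pd.Series,
    anchor: str,
) -> tuple[pd.Series, pd.Series]:
    """Put SRS and TLC CE tables on a common artificial scale.

    Each table is divided by its own CE value in the ``anchor`` condition
    (conventionally the double cholesterol + oleic-acid load), so the anchor
    equals 1 in both tables by construction while all other entries keep
    their within-table ratios; remaining differences between the tables are
    genuine method discrepancies.
    """
    srs = pd.Series(srs_by_condition, dtype=float)
    tlc = pd.Series(tlc_by_condition, dtype=float)
    for name, table in (("SRS", srs), ("TLC", tlc)):
        if anchor not in table.index:
            raise ValueError(f"anchor condition {anchor!r} missing from {name} table")
        if table[anchor] <= 0:
            raise ValueError(f"{name} anchor value must be > 0")
    return srs / srs[anchor], tlc / tlc[anchor]


def compare_groups(
    a: Sequence[float],
    b: Sequence[float],
    test: str = "welch",
) -> dict[str, float]:
    """Two-group comparison used in figure-style statistics.

    ``test="welch"`` is the unequal-variance t-test used for CE fractions
    and lipid intensities; ``test="mannwhitney"`` is the Mann-Whitney U test
    used for NE-LD counts.  Degenerate zero-variance inputs are handled with
    a tiny variance floor instead of returning NaN.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    mean_a, mean_b = float(a.mean()), float(b.mean())
    if test == "welch":
        with warnings.catch_warnings():
            # near-constant groups trigger a precision warning; the NaN
            # fallback below handles the fully degenerate case explicitly
            warnings.simplefilter("ignore", RuntimeWarning)
            stat, p = scipy.stats.ttest_ind(a, b, equal_var=False)
        if np.isnan(stat):  # zero variance in both groups
            eps = 1e-24
            se = np.sqrt(a.var(ddof=1) / a.size + b.var(ddof=1) / b.size + eps)
            stat = (mean_a - mean_b) / se
            df = a.size + b.size - 2
            p = 2 * scipy.stats.t.sf(abs(stat), df)
    elif test == "mannwhitney":
        stat, p = scipy.stats.mannwhitneyu(a, b, alternative="two-sided")
    else:
        raise ValueError(f"unknown test {test!r}")
    return {
        "mean_a": mean_a,
        "mean_b": mean_b,
        "mean_difference": mean_a - mean_b,
        "statistic": float(stat),
        "p_value": float(p),
    }


def compare_ne_vs_cyto(records: Sequence[DropletRecord]) -> dict[str, float]:
    """Welch t-test on CE fraction: NE-LDs vs cytoplasmic LDs.

    Returns means for both groups (``mean_a`` = NE), the mean difference,
    the t statistic and two-sided p value.
    """
    ne = [r.ce_fraction for r in records if r.is_ne and not np.isnan(r.ce_fraction)]
    cyto = [r.ce_fraction for r in records if not r.is_ne and not np.isnan(r.ce_fraction)]
    if len(ne) < 2 or len(cyto) < 2:
        raise ValueError("both NE and cytoplasmic groups need >= 2 droplets")
    out = compare_groups(ne, cyto, test="welch")
    out["n_ne"] = len(ne)
    out["n_cyto"] = len(cyto)
    return out
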