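"""Base-resolution classification of Hi-C paired-end reads.

Every paired-end read is an "arrow" pair in the 2D contact plane: each end
has a 5' start, a length and a strand, and points along its strand.  Reads
fall into ligation products (the four contact quadrants around a cut-site
intersection), non-ligation byproducts near the diagonal (dangling ends,
rejoined fragments, self-circles, random genomic DNA) or "other".

Coordinate conventions (used everywhere in the package):

* coordinates are 1-based inclusive;
* ``start`` is the 5' position of the mapped end; a ``+`` end covers
  ``[start, start + length - 1]``, a ``-`` end covers
  ``[start - length + 1, start]``;
* end 1 is upstream of end 2 (``start1 <= start2`` for converging pairs);
* a ``+`` end points toward the closest cut site at or downstream of its
  start; a ``-`` end toward the closest site at or upstream.

Classification rules (the prose definitions are normative):

* **dangling_L / dangling_R** — ends on opposite strands converging, with
  the 5' start of end 1 (resp. end 2) exactly on a cut site (within
  ``tol_dangling``): a digested, un-religated fragment.
* **rejoined** — a converging pair whose molecule span contains exactly one
  cut site: the original cut was re-ligated and the molecule spans it.
* **random** — converging pair on a single restriction fragment, touching
  no cut site: plain genomic DNA pointing toward the diagonal.
* **self_circle** — diverging pair whose two ends point to *neighboring*
  cut sites: ligation of the two ends of one fragment.  (Between
  neighboring cut sites, self-circles replace the close-contact quadrant.)
* **contact_up / down / close / far** — both ends point toward the cut-site
  intersection (i, j), i < j: up = both ends upstream of their sites
  (``+/+``), down = both downstream (``-/-``), close = diverging (``-/+``,
  nearer the diagonal than the intersection), far = converging (``+/-``,
  farther from the diagonal).
* **other** — an end's pointed-to cut site farther than
  ``max_cutsite_distance``, direction inconsistent with every category, or
  a read running off the cut-site map.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

CATEGORIES = (
    "dangling_L", "dangling_R", "rejoined", "self_circle", "random",
    "contact_up", "contact_down", "contact_close", "contact_far", "other",
)
CONTACT_CATEGORIES = ("contact_up", "contact_down", "contact_close", "contact_far")
#: quadrant label for each contact category, as used in count aggregation
QUADRANTS = ("up", "down", "close", "far")


@dataclass(frozen=True)
class CutSiteMap:
    """Sorted restriction cut-site coordinates on one chromosome."""

    chrom: str
    positions: np.ndarray  # 1-based, strictly increasing
    enzyme_name: str = "unknown"

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=np.int64)
        if pos.ndim != 1 or len(pos) == 0:
            raise ValueError("cut-site map needs a non-empty 1-D position vector")
        if np.any(np.diff(pos) <= 0):
            raise ValueError("cut-site positions must be strictly increasing")
        if pos[0] < 1:
            raise ValueError("cut-site positions are 1-based (>= 1)")
        object.__setattr__(self, "positions", pos)

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    def index_downstream(self, pos):
        """Index of the first cut site >= pos (len(positions) if none)."""
        return np.searchsorted(self.positions, pos, side="left")

    def index_upstream(self, pos):
        """Index of the last cut site <= pos (-1 if none)."""
        return np.searchsorted(self.positions, pos, side="right") - 1


class ClassifiedRead(NamedTuple):
    category: str
    site_i: int      # cut-site index (contacts: left anchor; else assigned site)
    site_j: int      # contacts: right anchor; -1 otherwise
    distance: int    # contacts: |pos_j - pos_i| in bp; 0 otherwise


@dataclass
class ClassificationParams:
    tol_dangling: int = 0
    max_cutsite_distance: int = 1000


def _as_strand(values) -> np.ndarray:
    s = np.where(np.asarray(values).astype(str) == "-", -1, 1)
    return s.astype(np.int8)


def classify_all(reads: pd.DataFrame, cutsites: CutSiteMap,
                 params: ClassificationParams | None = None,
                 ) -> tuple[pd.DataFrame, pd.Series]:
    """Classify every read; returns (classified table, category tally).

    Reads on a chromosome other than the cut-site map's (including trans
    pairs) are put in "other".  The tally always sums to ``len(reads)``.
    """
    if params is None:
        params = ClassificationParams()
    P = cutsites.positions
    n_sites = len(P)
    n = len(reads)

    out = reads.copy()
    if n == 0:
        out["category"] = pd.Series(dtype=str)
        for c in ("site_i", "site_j", "pos_i", "pos_j", "distance"):
            out[c] = pd.Series(dtype=np.int64)
        tally = pd.Series(0, index=list(CATEGORIES))
        return out, tally

    p1 = reads["start1"].to_numpy(np.int64)
    p2 = reads["start2"].to_numpy(np.int64)
    s1 = _as_strand(reads["strand1"])
    s2 = _as_strand(reads["strand2"])
    cis = ((reads["chrom1"].to_numpy(str) == cutsites.chrom)
           & (reads["chrom2"].to_numpy(str) == cutsites.chrom))

    # pointed-to cut-site index per end: + -> downstream, - -> upstream
    down1, up1 = cutsites.index_downstream(p1), cutsites.index_upstream(p1)
    down2, up2 = cutsites.index_downstream(p2), cutsites.index_upstream(p2)
    t1 = np.where(s1 > 0, down1, up1)
    t2 = np.where(s2 > 0, down2, up2)
    ok1 = (t1 >= 0) & (t1 < n_sites)
    ok2 = (t2 >= 0) & (t2 < n_sites)
    d1 = np.where(ok1, np.abs(P[np.clip(t1, 0, n_sites - 1)] - p1), np.iinfo(np.int64).max)
    d2 = np.where(ok2, np.abs(P[np.clip(t2, 0, n_sites - 1)] - p2), np.iinfo(np.int64).max)
    near1 = ok1 & (d1 <= params.max_cutsite_distance)
    near2 = ok2 & (d2 <= params.max_cutsite_distance)

    # exact (within tol) cut-site hits of the 5' starts, for dangling ends
    nd1 = np.minimum(np.where(down1 < n_sites, np.abs(P[np.clip(down1, 0, n_sites - 1)] - p1),
                              np.iinfo(np.int64).max),
                     np.where(up1 >= 0, np.abs(p1 - P[np.clip(up1, 0, n_sites - 1)]),
                              np.iinfo(np.int64).max))
    nd2 = np.minimum(np.where(down2 < n_sites, np.abs(P[np.clip(down2, 0, n_sites - 1)] - p2),
                              np.iinfo(np.int64).max),
                     np.where(up2 >= 0, np.abs(p2 - P[np.clip(up2, 0, n_sites - 1)]),
                              np.iinfo(np.int64).max))
    hit1 = nd1 <= params.tol_dangling
    hit2 = nd2 <= params.tol_dangling

    category = np.full(n, "other", dtype=object)
    site_i = np.full(n, -1, dtype=np.int64)
    site_j = np.full(n, -1, dtype=np.int64)

    conv = cis & (s1 > 0) & (s2 < 0) & (p1 <= p2)      # +/- converging
    div = cis & (s1 < 0) & (s2 > 0) & (p1 <= p2)       # -/+ diverging
    upup = cis & (s1 > 0) & (s2 > 0)
    dndn = cis & (s1 < 0) & (s2 < 0)

    # --- converging: dangling > rejoined / random / far contact ---
    dl = conv & hit1
    dr = conv & ~hit1 & hit2
    category[dl] = "dangling_L"
    # nearest site to the hit (within tol): pick the closer of up/down
    _near_idx1 = np.where(
        np.where(down1 < n_sites, np.abs(P[np.clip(down1, 0, n_sites - 1)] - p1),
                 np.iinfo(np.int64).max)
        <= np.where(up1 >= 0, np.abs(p1 - P[np.clip(up1, 0, n_sites - 1)]),
                    np.iinfo(np.int64).max),
        np.clip(down1, 0, n_sites - 1), np.clip(up1, 0, n_sites - 1))
    _near_idx2 = np.where(
        np.where(down2 < n_sites, np.abs(P[np.clip(down2, 0, n_sites - 1)] - p2),
                 np.iinfo(np.int64).max)
        <= np.where(up2 >= 0, np.abs(p2 - P[np.clip(up2, 0, n_sites - 1)]),
                    np.iinfo(np.int64).max),
        np.clip(down2, 0, n_sites - 1), np.clip(up2, 0, n_sites - 1))
    site_i[dl] = _near_idx1[dl]
    category[dr] = "dangling_R"
    site_i[dr] = _near_idx2[dr]

    rest = conv & ~hit1 & ~hit2
    both_near = near1 & near2
    same_frag = rest & (t1 > t2) & both_near          # no site inside the span
    spans_one = rest & (t1 == t2) & both_near         # exactly one site inside
    far = rest & (t1 < t2) & both_near & ok1 & ok2
    category[same_frag] = "random"
    site_i[same_frag] = np.clip(t2[same_frag], 0, n_sites - 1)  # fragment left edge
    category[spans_one] = "rejoined"
    site_i[spans_one] = t1[spans_one]
    category[far] = "contact_far"
    site_i[far] = t1[far]
    site_j[far] = t2[far]

    # --- diverging: self-circle (neighboring sites) or close contact ---
    dv = div & ok1 & ok2 & near1 & near2 & (t2 > t1)
    sc = dv & (t2 == t1 + 1)
    cl = dv & (t2 > t1 + 1)
    category[sc] = "self_circle"
    site_i[sc] = t1[sc]
    site_j[sc] = t2[sc]
    category[cl] = "contact_close"
    site_i[cl] = t1[cl]
    site_j[cl] = t2[cl]

    # --- same-strand: up / down contacts ---
    for mask, name in ((upup, "contact_up"), (dndn, "contact_down")):
        m = mask & ok1 & ok2 & near1 & near2 & (t1 < t2)
        category[m] = name
        site_i[m] = t1[m]
        site_j[m] = t2[m]

    is_contact = np.isin(category, CONTACT_CATEGORIES) | (category == "self_circle")
    pos_i = np.where(site_i >= 0, P[np.clip(site_i, 0, n_sites - 1)], -1)
    pos_j = np.where(site_j >= 0, P[np.clip(site_j, 0, n_sites - 1)], -1)
    distance = np.where(is_contact & (site_j >= 0), pos_j - pos_i, 0)

    out["category"] = category
    out["site_i"] = site_i
    out["site_j"] = site_j
    out["pos_i"] = pos_i
    out["pos_j"] = pos_j
    out["distance"] = distance
    tally = out["category"].value_counts().reindex(list(CATEGORIES), fill_value=0)
    return out, tally


def classify_read(read, cutsites: CutSiteMap,
                  tol_dangling: int = 0,
                  max_cutsite_distance: int = 1000) -> ClassifiedRead:
    """Classify a single read (mapping or dict with the 12 intersection fields).

    Raises ``ValueError`` if the read is not on the cut-site map's chromosome.
    """
    rec = dict(read)
    if str(rec["chrom1"]) != cutsites.chrom or str(rec["chrom2"]) != cutsites.chrom:
        raise ValueError(
            f"read on {rec['chrom1']}/{rec['chrom2']}, cut sites on {cutsites.chrom}")
    df = pd.DataFrame([rec])
    params = ClassificationParams(tol_dangling, max_cutsite_distance)
    classified, _ = classify_all(df, cutsites, params)
    row = classified.iloc[0]
    return ClassifiedRead(row["category"], int(row["site_i"]), int(row["site_j"]),
                          int(row["distance"]))


_DUP_KEY = ["chrom1", "start1", "length1", "strand1",
            "chrom2", "start2", "length2", "strand2"]


def deduplicate_reads(reads: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Collapse PCR duplicates: identical (chrom, start, length, strand) on
    both ends.  Returns the deduplicated table and the number removed."""
    deduped = reads.drop_duplicates(subset=_DUP_KEY, keep="first")
    return deduped.reset_index(drop=True), len(reads) - len(deduped)


def filter_short_range(classified: pd.DataFrame, min_distance: int = 1000
                       ) -> pd.DataFrame:
    """Drop contact reads whose anchors are closer than ``min_distance`` bp.

    Contacts below ~1 kb cannot be separated from religation byproducts and
    are excluded from the model.  Non-contact categories pass through.
    """
    is_contact = classified["category"].isin(CONTACT_CATEGORIES)
    keep = ~is_contact | (classified["distance"] >= min_distance)
    return classified[keep].reset_index(drop=True)


_DIAGONAL_CATEGORIES = ("dangling_L", "dangling_R", "rejoined", "random")


def sonication_length_histogram(classified: pd.DataFrame, bin_width: int = 10
                                ) -> pd.Series:
    """Sonication fragment-length spectrum from reads near the diagonal.

    The molecule length of a converging near-diagonal pair (dangling,
    rejoined, random) is ``start2 - start1 + 1``.  Returns counts indexed by
    bin left edge; the total equals the number of contributing reads.
    """
    sel = classified[classified["category"].isin(_DIAGONAL_CATEGORIES)]
    if len(sel) == 0:
        return pd.Series(dtype=np.int64)
    lengths = (sel["start2"] - sel["start1"] + 1).to_numpy()
    bins = (lengths // bin_width) * bin_width
    return pd.Series(bins).value_counts().sort_index()


def dangling_position_histogram(classified: pd.DataFrame, cutsites: CutSiteMap
                                ) -> pd.Series:
    """Offsets of dangling-end 5' starts from their assigned cut site.

    Sharp spikes identify the enzyme's cutting offset; secondary peaks hint
    at degradation or processing problems.  Offset = 5' start − cut-site
    coordinate of the assigned site.
    """
    P = cutsites.positions
    offsets = []
    dl = classified[classified["category"] == "dangling_L"]
    if len(dl):
        offsets.append(dl["start1"].to_numpy(np.int64) - P[dl["site_i"].to_numpy()])
    dr = classified[classified["category"] == "dangling_R"]
    if len(dr):
        offsets.append(dr["start2"].to_numpy(np.int64) - P[dr["site_i"].to_numpy()])
    if not offsets:
        return pd.Series(dtype=np.int64)
    return pd.Series(np.concatenate(offsets)).value_counts().sort_index()


@dataclass
class AggregatedCounts:
    """Per-cut-site byproduct counts and per-pair contact counts."""

    cutsite_counts: pd.DataFrame   # index: site; columns dangling_L/_R, rejoined
    contacts: pd.DataFrame         # columns site_i, site_j, category, count
    other_tally: pd.Series = field(default_factory=lambda: pd.Series(dtype=np.int64))


def aggregate_counts(classified: pd.DataFrame, cutsites: CutSiteMap
                     ) -> AggregatedCounts:
    """Aggregate classified reads to cut-site level.

    Dangling and rejoined reads are counted per assigned cut site (d_i);
    contact reads per (i, j, quadrant) cut-site intersection (c_ij).
    Self-circle, random and other reads are tallied but not modeled.
    Conservation: the sum of all returned counts equals ``len(classified)``.
    """
    n_sites = cutsites.n_sites
    counts = pd.DataFrame(
        0, index=np.arange(n_sites),
        columns=["dangling_L", "dangling_R", "rejoined"], dtype=np.int64)
    for cat in ("dangling_L", "dangling_R", "rejoined"):
        sel = classified[(classified["category"] == cat) & (classified["site_i"] >= 0)]
        if len(sel):
            binc = np.bincount(sel["site_i"].to_numpy(), minlength=n_sites)
            counts[cat] = binc
    is_contact = classified["category"].isin(CONTACT_CATEGORIES)
    con = classified[is_contact]
    if len(con):
        quadrant = con["category"].str.replace("contact_", "", regex=False)
        grouped = (pd.DataFrame({"site_i": con["site_i"], "site_j": con["site_j"],
                                 "category": quadrant})
                   .groupby(["site_i", "site_j", "category"], observed=True)
                   .size().rename("count").reset_index())
    else:
        grouped = pd.DataFrame({"site_i": pd.Series(dtype=np.int64),
                                "site_j": pd.Series(dtype=np.int64),
                                "category": pd.Series(dtype=str),
                                "count": pd.Series(dtype=np.int64)})
    other = classified[~is_contact
                       & ~classified["category"].isin(("dangling_L", "dangling_R",
                                                       "rejoined"))]
    other_tally = other["category"].value_counts()
    # reads assigned to a dangling/rejoined category but off the map edge
    lost = classified[classified["category"].isin(("dangling_L", "dangling_R",
                                                   "rejoined"))
                      & (classified["site_i"] < 0)]
    if len(lost):
        other_tally = other_tally.add(pd.Series({"other": len(lost)}), fill_value=0)
    return AggregatedCounts(counts, grouped, other_tally.astype(np.int64))
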