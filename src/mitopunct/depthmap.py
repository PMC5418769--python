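"""Per-base depth profiles, punctuation expression and heteroplasmy calling.

A :class:`BaseCountProfile` tallies aligned read bases (A/C/G/T only;
deletions, skips and N calls contribute nothing) per reference position.
Heteroplasmic sites are called with three strict conditions: more than one
nucleotide observed at the position, more than ``min_depth`` supporting
reads, and the second most frequent base at a frequency strictly above
``min_minor_freq``.  With the defaults (100 reads, 10%) every called site
is necessarily supported by at least 10 minor-allele reads — a derived
bound, not a fourth condition.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Sequence, TYPE_CHECKING

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from mitopunct.synthetic import Feature

logger = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


class MalformedAlignmentError(ValueError):
    """Raised when more than the tolerated fraction of records is unusable."""


class BaseCountProfile:
    """Per-position base counts; ``counts`` is an (L, 4) array over A,C,G,T."""

    def __init__(self, counts: np.ndarray):
        counts = np.asarray(counts, dtype=np.int64)
        if counts.ndim != 2 or counts.shape[1] != 4:
            raise ValueError("counts must have shape (L, 4)")
        if (counts < 0).any():
            raise ValueError("negative base counts")
        self.counts = counts

    def __len__(self) -> int:
        return self.counts.shape[0]

    @property
    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_sam(cls, path: str | Path, reference_length: int,
                 max_malformed_frac: float = 0.10) -> "BaseCountProfile":
        """Tally base counts from a SAM file (M/=/X columns only).

        Malformed records are skipped with a warning; if more than
        ``max_malformed_frac`` of records are malformed the build aborts.
        """
        import pysam

        counts = np.zeros((reference_length, 4), dtype=np.int64)
        total = malformed = 0
        with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
            for read in sam:
                if read.is_unmapped:
                    continue
                total += 1
                try:
                    seq = read.query_sequence
                    if seq is None:
                        raise ValueError("missing SEQ")
                    for qpos, rpos in read.get_aligned_pairs(matches_only=True):
                        if rpos >= reference_length:
                            raise ValueError("alignment beyond reference end")
                        idx = _BASE_INDEX.get(seq[qpos].upper())
                        if idx is not None:
                            counts[rpos, idx] += 1
                except (ValueError, IndexError, TypeError) as exc:
                    malformed += 1
                    logger.warning("skipping malformed record %s: %s",
                                   read.query_name, exc)
        if total and malformed / total > max_malformed_frac:
            raise MalformedAlignmentError(
                f"{malformed}/{total} records malformed")
        return cls(counts)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "BaseCountProfile":
        """Read a base-count TSV with columns pos, A, C, G, T (N optional)."""
        df = pd.read_csv(path, sep="\t")
        df = df.sort_values("pos")
        length = int(df["pos"].max()) + 1 if len(df) else 0
        counts = np.zeros((length, 4), dtype=np.int64)
        counts[df["pos"].to_numpy()] = df[list(BASES)].to_numpy()
        return cls(counts)

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.counts, columns=list(BASES))
        df.insert(0, "pos", np.arange(len(self)))
        df["N"] = 0
        df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# depth summaries
# ---------------------------------------------------------------------------

def _median_nonzero(depth: np.ndarray) -> float:
    covered = depth[depth > 0]
    return float(np.median(covered)) if covered.size else math.nan


def depth_summary(profile: BaseCountProfile,
                  features: Sequence["Feature"] | None = None) -> dict:
    """Genome-wide and per-feature depth statistics.

    Medians and means are computed over positions with non-zero coverage;
    the even-count median is the midpoint of the two central values.
    """
    if len(profile) == 0:
        raise ValueError("empty profile")
    depth = profile.depth
    covered = depth[depth > 0]
    summary = {
        "genome_median": _median_nonzero(depth),
        "genome_mean": float(covered.mean()) if covered.size else math.nan,
        "covered_positions": int(covered.size),
        "length": len(profile),
        "per_feature": {},
    }
    for f in features or ():
        summary["per_feature"][f.name] = _median_nonzero(depth[f.start:f.end])
    return summary


# ---------------------------------------------------------------------------
# heteroplasmy calling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HeteroplasmySite:
    position: int
    major_base: str
    major_count: int
    minor_base: str
    minor_count: int
    depth: int
    minor_freq: float
    triallelic: bool = False


def passes_conditions(counts: Sequence[int], min_depth: int = 100,
                      min_minor_freq: float = 0.10) -> bool:
    """Literal application of the three heteroplasmy conditions to one site.

    ``counts`` are the A/C/G/T tallies.  Conditions: (1) more than one base
    observed; (2) depth strictly greater than ``min_depth``; (3) frequency of
    the second most frequent base strictly greater than ``min_minor_freq``.
    Frequencies are compared in exact rational arithmetic so threshold-equal
    sites are never called.
    """
    depth = int(sum(counts))
    if depth <= min_depth:
        return False
    ordered = sorted(counts, reverse=True)
    minor = int(ordered[1])
    if minor == 0:
        return False  # monoallelic
    return Fraction(minor, depth) > Fraction(str(min_minor_freq))


def call_heteroplasmic_sites(
    profile: BaseCountProfile,
    min_depth: int = 100,
    min_minor_freq: float = 0.10,
) -> list[HeteroplasmySite]:
    """Positions satisfying all three conditions, strict inequalities.

    The minor base is the second most frequent base (ties broken
    alphabetically); a site where a third base also clears the frequency
    bar is flagged triallelic.  The frequency denominator is the sum of
    A/C/G/T counts at the position.
    """
    counts = profile.counts
    depth = counts.sum(axis=1)
    part = np.sort(counts, axis=1)  # ascending
    minor = part[:, 2]
    threshold = Fraction(str(min_minor_freq))
    # exact rational comparison, vectorized: minor/depth > num/den
    candidate = (
        (depth > min_depth)
        & (minor > 0)
        & (minor * threshold.denominator > depth * threshold.numerator)
    )
    sites: list[HeteroplasmySite] = []
    for pos in np.flatnonzero(candidate):
        row = counts[pos]
        order = sorted(range(4), key=lambda i: (-row[i], BASES[i]))
        maj, mnr, third = order[0], order[1], order[2]
        d = int(depth[pos])
        tri = (row[third] > 0
               and Fraction(int(row[third]), d) > threshold)
        sites.append(HeteroplasmySite(
            position=int(pos),
            major_base=BASES[maj], major_count=int(row[maj]),
            minor_base=BASES[mnr], minor_count=int(row[mnr]),
            depth=d, minor_freq=int(row[mnr]) / d,
            triallelic=bool(tri)))
    return sites


def write_heteroplasmy_tsv(
    sites: Iterable[HeteroplasmySite],
    path: str | Path,
    features: Sequence["Feature"] | None = None,
    counts: np.ndarray | None = None,
) -> None:
    """One row per site: position, gene, total reads, per-base counts and
    proportions."""
    def gene_at(pos: int) -> str:
        for f in features or ():
            if f.start <= pos < f.end:
                return f.name
        return "intergenic"

    rows = []
    for s in sites:
        row = {"position": s.position, "gene": gene_at(s.position),
               "total_reads": s.depth,
               "major_base": s.major_base, "minor_base": s.minor_base,
               "minor_freq": round(s.minor_freq, 4),
               "triallelic": s.triallelic}
        if counts is not None:
            for i, b in enumerate(BASES):
                c = int(counts[s.position, i])
                row[f"{b}_count"] = c
                row[f"{b}_prop"] = round(c / s.depth, 4)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# punctuation expression profile
# ---------------------------------------------------------------------------

def punctuation_profile(
    profile: BaseCountProfile,
    features: Sequence["Feature"],
) -> pd.DataFrame:
    """Per-feature median depth and boundary fold-changes.

    Returns one row per annotated feature with its median depth and the
    log2 fold-change across the boundary to the next feature.  The
    bicistronic pairs nad4l/nad4 and atp8/atp6 are flagged as expected to
    be co-expressed (boundary fold-change near zero under the punctuation
    model).
    """
    from mitopunct.synthetic import BICISTRONIC_PAIRS

    depth = profile.depth
    ordered = sorted(features, key=lambda f: f.start)
    medians = [_median_nonzero(depth[f.start:f.end]) for f in ordered]
    coupled = set(BICISTRONIC_PAIRS)
    rows = []
    for i, f in enumerate(ordered):
        nxt = ordered[i + 1] if i + 1 < len(ordered) else None
        if nxt is not None and medians[i] and medians[i + 1] \
                and not math.isnan(medians[i]) and not math.isnan(medians[i + 1]):
            log2fc = math.log2(medians[i + 1] / medians[i])
        else:
            log2fc = math.nan
        rows.append({
            "feature": f.name,
            "median_depth": medians[i],
            "next_feature": nxt.name if nxt else None,
            "boundary_log2fc": log2fc,
            "expected_coupled": (nxt is not None
                                 and (f.name, nxt.name) in coupled),
        })
    return pd.DataFrame(rows)
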