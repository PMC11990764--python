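"""Parent-of-origin assignment from haplotype-tagged read evidence.

Long-read aligners plus a haplotagger (e.g. WhatsHap haplotag) label each read
spanning a de novo variant with the parental haplotype it derives from.  This
module turns those labels into a parent-of-origin call per variant and into
the haplotype-specific VAF — the alt fraction among reads of the mutated
haplotype — which is ~1 for constitutional variants and drops below 1 when
the child is postzygotically mosaic.
"""

from __future__ import annotations

from dataclasses import dataclass

import math

import pandas as pd

HAPLOTYPES = ("paternal", "maternal", "untagged")


class PhasingContractError(ValueError):
    """Raised when an operation is called with an origin it cannot use."""


@dataclass(frozen=True)
class TaggedReadEvidence:
    """All tagged reads overlapping one variant."""

    variant_key: str
    reads: tuple[tuple[str, str, bool], ...]   # (read_id, haplotype, carries_alt)

    def __post_init__(self) -> None:
        ids = [r[0] for r in self.reads]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate read ids for {self.variant_key}")
        for _, hap, _ in self.reads:
            if hap not in HAPLOTYPES:
                raise ValueError(f"unknown haplotype tag {hap!r}")

    def counts(self) -> dict[str, dict[str, int]]:
        out = {h: {"alt": 0, "ref": 0} for h in HAPLOTYPES}
        for _, hap, alt in self.reads:
            out[hap]["alt" if alt else "ref"] += 1
        return out


@dataclass
class PhasedDNM:
    variant_key: str
    parent_of_origin: str          # paternal | maternal | unphased | conflict
    n_alt_pat: int
    n_alt_mat: int
    n_ref_origin_hap: int
    origin_hap_depth: int
    haplotype_specific_vaf: float  # NaN when undefined


def assign_parent_of_origin(evidence: TaggedReadEvidence,
                            min_alt_reads: int = 3,
                            max_minor_fraction: float = 0.1) -> str:
    """Call the parental haplotype carrying the variant.

    Requires at least ``min_alt_reads`` haplotagged alt-bearing reads, with
    the minority haplotype holding at most ``max_minor_fraction`` of them;
    substantial alt evidence on both haplotypes is a ``conflict`` (possible
    tagging error or tandem event), insufficient evidence is ``unphased``.
    """
    c = evidence.counts()
    alt_pat, alt_mat = c["paternal"]["alt"], c["maternal"]["alt"]
    total_alt = alt_pat + alt_mat
    if total_alt < min_alt_reads:
        return "unphased"
    minor = min(alt_pat, alt_mat)
    if minor / total_alt > max_minor_fraction:
        return "conflict"
    return "paternal" if alt_pat > alt_mat else "maternal"


def haplotype_specific_vaf(evidence: TaggedReadEvidence,
                           parent_of_origin: str) -> tuple[float, int]:
    """Alt fraction among reads tagged with the origin haplotype.

    Untagged reads are uninformative and excluded from both numerator and
    denominator.  Returns (NaN, 0) when no origin-haplotype reads exist.
    """
    if parent_of_origin not in ("paternal", "maternal"):
        raise PhasingContractError(
            f"haplotype-specific VAF needs a determined origin, got "
            f"{parent_of_origin!r}")
    c = evidence.counts()[parent_of_origin]
    depth = c["alt"] + c["ref"]
    if depth == 0:
        return math.nan, 0
    return c["alt"] / depth, depth


def evidence_from_frame(frame: pd.DataFrame) -> dict[str, TaggedReadEvidence]:
    """Group a tagged-read table (variant_key, read_id, haplotype,
    carries_alt) into per-variant evidence objects."""
    out = {}
    for key, group in frame.groupby("variant_key", sort=False):
        reads = tuple((str(r.read_id), str(r.haplotype), bool(r.carries_alt))
                      for r in group.itertuples())
        out[key] = TaggedReadEvidence(variant_key=key, reads=reads)
    return out


def phase_cohort(evidence_frame: pd.DataFrame, dnm_table: pd.DataFrame,
                 min_alt_reads: int = 3,
                 max_minor_fraction: float = 0.1) -> tuple[pd.DataFrame, dict]:
    """Phase every DNM in the table.

    Variants with no evidence rows are unphased.  Orphan evidence keys (not
    in the DNM table) are counted, not fatal.  Returns the phased table and a
    summary with per-trio and cohort phasing rate and paternal fraction
    (fraction of *phased* variants that are paternal).
    """
    evidence = evidence_from_frame(evidence_frame) if len(evidence_frame) else {}
    known = set(dnm_table.variant_key)
    orphans = sorted(k for k in evidence if k not in known)

    rows = []
    for row in dnm_table.itertuples():
        ev = evidence.get(row.variant_key)
        if ev is None or not ev.reads:
            rows.append({"variant_key": row.variant_key,
                         "parent_of_origin": "unphased",
                         "n_alt_pat": 0, "n_alt_mat": 0,
                         "n_ref_origin_hap": 0, "origin_hap_depth": 0,
                         "haplotype_specific_vaf": math.nan})
            continue
        origin = assign_parent_of_origin(ev, min_alt_reads, max_minor_fraction)
        c = ev.counts()
        if origin in ("paternal", "maternal"):
            hvaf, depth = haplotype_specific_vaf(ev, origin)
            n_ref = c[origin]["ref"]
        else:
            hvaf, depth, n_ref = math.nan, 0, 0
        rows.append({"variant_key": row.variant_key,
                     "parent_of_origin": origin,
                     "n_alt_pat": c["paternal"]["alt"],
                     "n_alt_mat": c["maternal"]["alt"],
                     "n_ref_origin_hap": n_ref,
                     "origin_hap_depth": depth,
                     "haplotype_specific_vaf": hvaf})
    phased = dnm_table.merge(pd.DataFrame(rows, columns=[
        "variant_key", "parent_of_origin", "n_alt_pat", "n_alt_mat",
        "n_ref_origin_hap", "origin_hap_depth", "haplotype_specific_vaf"]),
        on="variant_key", how="left")

    def rates(sub: pd.DataFrame) -> dict:
        n = len(sub)
        phased_mask = sub.parent_of_origin.isin(["paternal", "maternal"])
        n_phased = int(phased_mask.sum())
        n_pat = int((sub.parent_of_origin == "paternal").sum())
        return {"n": n, "n_phased": n_phased,
                "phasing_rate": n_phased / n if n else 0.0,
                "paternal_fraction": n_pat / n_phased if n_phased else math.nan}

    summary = {"cohort": rates(phased), "orphan_evidence_keys": orphans,
               "per_trio": {}}
    if "trio_id" in phased.columns:
        for trio, sub in phased.groupby("trio_id"):
            summary["per_trio"][trio] = rates(sub)
    return phased, summary
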