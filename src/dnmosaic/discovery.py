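"""Trio-based de novo mutation discovery.

Implements the high-confidence DNM filter cascade over joint-called trio
genotypes, 20 kb mutational-cluster detection, and the clustered versus
non-clustered Ti/Tv summary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .config import Thresholds

MEMBERS = ("child", "father", "mother")

#: canonical filter evaluation order (reporting only; the cascade is a pure
#: conjunction so pass/fail is order independent)
FILTER_NAMES = ("genotype", "depth", "genotype_quality", "child_vaf",
                "biallelic_fraction", "vaf_shift")

_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}


class MalformedRecordError(ValueError):
    """A genotype record field could not be interpreted; names the sample."""


@dataclass(frozen=True)
class MemberGenotype:
    """One sample's call at one site: genotype, depth, quality, allelic depths."""

    genotype: tuple[int, ...] | None   # None = missing call
    dp: int | None
    gq: int | None
    ad: tuple[int, ...] | None

    @property
    def vaf(self) -> float | None:
        """Alt depth over total depth; None when DP or AD is unusable."""
        if self.ad is None or self.dp is None or self.dp <= 0:
            return None
        if len(self.ad) < 2:
            return None
        return self.ad[1] / self.dp


@dataclass(frozen=True)
class TrioGenotypeRecord:
    """One biallelic VCF site with the three family members' calls."""

    chrom: str
    pos: int
    ref: str
    alt: str
    members: dict[str, MemberGenotype]

    @property
    def variant_key(self) -> str:
        return f"{self.chrom}-{self.pos}-{self.ref}-{self.alt}"

    @property
    def variant_type(self) -> str:
        return "SNV" if len(self.ref) == 1 and len(self.alt) == 1 else "indel"


@dataclass
class FilterResult:
    passed: bool
    trail: list[tuple[str, bool]]          # (filter name, passed) in order
    first_failure: str | None = None


@dataclass
class DNMCandidate:
    """A site that survived every trio filter."""

    variant_key: str
    trio_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    variant_type: str
    child_vaf: float
    father_vaf: float
    mother_vaf: float
    review: str = "accepted"
    filter_trail: list[tuple[str, bool]] = field(default_factory=list)
    non_autosomal: bool = False


def apply_trio_filters(record: TrioGenotypeRecord,
                       thresholds: Thresholds = Thresholds()) -> FilterResult:
    """Run the six-filter cascade on one trio record.

    Pass requires: child heterozygous alt with both parents homozygous
    reference; depth strictly above ``min_depth`` and genotype quality
    strictly above ``min_gq`` in all three members; child VAF strictly above
    ``min_child_vaf``; ref+alt allelic depths above ``biallelic_fraction`` of
    DP in all members (multi-allelic contamination guard); and the child VAF
    at least ``vaf_shift`` times each parent's VAF (a zero parent VAF passes,
    which is what lets parental mosaics through to the deep-count stage).
    """
    m = record.members
    for name in MEMBERS:
        if name not in m:
            raise MalformedRecordError(f"missing member {name!r}")
        g = m[name]
        if g.ad is not None and (len(g.ad) < 2 or any(a < 0 for a in g.ad)):
            raise MalformedRecordError(f"malformed AD for sample {name!r}: {g.ad}")

    trail: list[tuple[str, bool]] = []

    def complete(g: MemberGenotype) -> bool:
        return (g.genotype is not None and g.dp is not None
                and g.gq is not None and g.ad is not None)

    ok_fields = all(complete(m[n]) for n in MEMBERS)
    genotype_ok = (ok_fields
                   and sorted(m["child"].genotype) == [0, 1]
                   and m["father"].genotype == (0, 0)
                   and m["mother"].genotype == (0, 0))
    trail.append(("genotype", genotype_ok))

    depth_ok = ok_fields and all(m[n].dp > thresholds.min_depth for n in MEMBERS)
    trail.append(("depth", depth_ok))

    gq_ok = ok_fields and all(m[n].gq > thresholds.min_gq for n in MEMBERS)
    trail.append(("genotype_quality", gq_ok))

    child_vaf = m["child"].vaf
    vaf_ok = ok_fields and child_vaf is not None and child_vaf > thresholds.min_child_vaf
    trail.append(("child_vaf", vaf_ok))

    def biallelic(g: MemberGenotype) -> bool:
        return (g.ad is not None and g.dp is not None and g.dp > 0
                and (g.ad[0] + g.ad[1]) > thresholds.biallelic_fraction * g.dp)

    bi_ok = ok_fields and all(biallelic(m[n]) for n in MEMBERS)
    trail.append(("biallelic_fraction", bi_ok))

    def shift_ok(parent: str) -> bool:
        pv = m[parent].vaf
        if pv is None or child_vaf is None:
            return False
        if pv == 0:
            return True
        return child_vaf >= thresholds.vaf_shift * pv

    sh_ok = ok_fields and shift_ok("father") and shift_ok("mother")
    trail.append(("vaf_shift", sh_ok))

    passed = all(ok for _, ok in trail)
    first = next((name for name, ok in trail if not ok), None)
    return FilterResult(passed=passed, trail=trail, first_failure=first)


def normalize_variant(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Left-align an indel representation by trimming shared suffix then
    shared prefix (keeping at least one base each side)."""
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


_AUTOSOMES = {f"chr{i}" for i in range(1, 23)} | {str(i) for i in range(1, 23)}


def call_dnms(records, trio_id: str,
              thresholds: Thresholds = Thresholds()) -> tuple[list[DNMCandidate], dict]:
    """Apply the cascade over a stream of trio records.

    Returns the sorted, deduplicated candidate list and a summary with SNV /
    indel counts, records seen, and counts of hom-alt Mendelian-double-hit
    sites (excluded) and non-autosomal candidates (kept, flagged).
    """
    seen: dict[str, DNMCandidate] = {}
    summary = {"records_seen": 0, "pass": 0, "snv": 0, "indel": 0,
               "hom_alt_excluded": 0, "non_autosomal": 0,
               "fail_by_filter": {name: 0 for name in FILTER_NAMES}}
    for record in records:
        summary["records_seen"] += 1
        result = apply_trio_filters(record, thresholds)
        if not result.passed:
            child = record.members.get("child")
            if (child is not None and child.genotype is not None
                    and set(child.genotype) == {1}
                    and record.members["father"].genotype == (0, 0)
                    and record.members["mother"].genotype == (0, 0)):
                summary["hom_alt_excluded"] += 1
            summary["fail_by_filter"][result.first_failure] += 1
            continue
        pos, ref, alt = normalize_variant(record.pos, record.ref, record.alt)
        key = f"{record.chrom}-{pos}-{ref}-{alt}"
        if key in seen:
            continue
        non_auto = record.chrom not in _AUTOSOMES
        cand = DNMCandidate(
            variant_key=key, trio_id=trio_id, chrom=record.chrom, pos=pos,
            ref=ref, alt=alt, variant_type=record.variant_type,
            child_vaf=record.members["child"].vaf,
            father_vaf=record.members["father"].vaf or 0.0,
            mother_vaf=record.members["mother"].vaf or 0.0,
            filter_trail=result.trail, non_autosomal=non_auto)
        seen[key] = cand
        summary["pass"] += 1
        summary["snv" if cand.variant_type == "SNV" else "indel"] += 1
        if non_auto:
            summary["non_autosomal"] += 1
    candidates = sorted(seen.values(), key=lambda c: (c.chrom, c.pos, c.ref, c.alt))
    return candidates, summary


def candidates_to_frame(candidates: list[DNMCandidate]) -> pd.DataFrame:
    rows = [{
        "variant_key": c.variant_key, "trio_id": c.trio_id, "chrom": c.chrom,
        "pos": c.pos, "ref": c.ref, "alt": c.alt, "variant_type": c.variant_type,
        "child_vaf": c.child_vaf, "father_vaf": c.father_vaf,
        "mother_vaf": c.mother_vaf, "review": c.review,
        "filter_trail": ";".join(f"{n}={'pass' if ok else 'fail'}"
                                 for n, ok in c.filter_trail),
    } for c in candidates]
    return pd.DataFrame(rows, columns=[
        "variant_key", "trio_id", "chrom", "pos", "ref", "alt", "variant_type",
        "child_vaf", "father_vaf", "mother_vaf", "review", "filter_trail"])


@dataclass
class MutationCluster:
    trio_id: str
    chrom: str
    member_keys: list[str]
    positions: list[int]
    parent_of_origin: str | None = None   # uniform origin, when known

    @property
    def span_bp(self) -> int:
        return self.positions[-1] - self.positions[0]

    @property
    def size(self) -> int:
        return len(self.member_keys)


def detect_clusters(candidates: pd.DataFrame,
                    gap_bp: int = 20_000) -> list[MutationCluster]:
    """Maximal single-linkage chains of same-trio, same-chromosome variants
    with adjacent gaps <= ``gap_bp``.  Singletons are not clusters.

    Accepts any frame with trio_id / chrom / pos / variant_key columns
    (optionally parent_of_origin, echoed when uniform within a cluster).
    """
    clusters: list[MutationCluster] = []
    has_origin = "parent_of_origin" in candidates.columns
    for (trio, chrom), group in candidates.groupby(["trio_id", "chrom"], sort=True):
        group = group.sort_values("pos")
        chain: list[pd.Series] = []
        def flush():
            if len(chain) >= 2:
                origin = None
                if has_origin:
                    origins = {r["parent_of_origin"] for r in chain}
                    if len(origins) == 1:
                        origin = origins.pop()
                clusters.append(MutationCluster(
                    trio_id=trio, chrom=chrom,
                    member_keys=[r["variant_key"] for r in chain],
                    positions=[int(r["pos"]) for r in chain],
                    parent_of_origin=origin))
            chain.clear()
        for _, row in group.iterrows():
            if chain and row["pos"] - chain[-1]["pos"] > gap_bp:
                flush()
            chain.append(row)
        flush()
    return clusters


def is_transition(ref: str, alt: str) -> bool:
    """A<->G or C<->T single-base substitution."""
    return ({ref, alt} <= _PURINES) or ({ref, alt} <= _PYRIMIDINES)


def titv_summary(candidates: pd.DataFrame,
                 clusters: list[MutationCluster]) -> pd.DataFrame:
    """Ti/Tv for clustered vs non-clustered SNVs.  A stratum with zero
    transversions reports ratio NaN (undefined, not infinite)."""
    clustered_keys = {k for cl in clusters for k in cl.member_keys}
    snvs = candidates[candidates["variant_type"] == "SNV"]
    rows = []
    for stratum, sub in (
            ("clustered", snvs[snvs.variant_key.isin(clustered_keys)]),
            ("non_clustered", snvs[~snvs.variant_key.isin(clustered_keys)])):
        ti = sum(is_transition(r, a) for r, a in zip(sub.ref, sub.alt))
        tv = len(sub) - ti
        ratio = ti / tv if tv > 0 else math.nan
        rows.append({"stratum": stratum, "n_snv": len(sub),
                     "transitions": ti, "transversions": tv, "titv": ratio})
    return pd.DataFrame(rows)
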