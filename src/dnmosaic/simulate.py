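"""Synthetic trio-cohort generator.

Emulates the full data footprint of a genome-wide parental-mosaicism study:
a truth table of de novo mutations (DNMs) with mutational-origin labels,
per-trio VCFs with the genotype fields the discovery filters consume, a
pedigree, haplotype-tagged long-read evidence for phasing, deduplicated deep
targeted count tables for mosaic testing, and a parental WGS pileup table for
the alt-read screen.  Everything is deterministic under a fixed seed.

The generator emits the *discovered* high-confidence DNM set: genotype fields
for true DNMs are sampled conditional on passing the trio filters, because the
truth table plays the role of the curated call set that the downstream stages
(phasing, deep-count testing, recurrence) take as input.  Borderline and
failing records for filter tests are constructed directly in the test suite.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import TISSUES, MosaicSpec, SimulationConfig

# hg38-like chromosome sizes, rounded to Mb; relative lengths set the DNM
# placement distribution, absolute values only bound positions.
_CHROM_SIZES = {
    "chr1": 248, "chr2": 242, "chr3": 198, "chr4": 190, "chr5": 181,
    "chr6": 171, "chr7": 159, "chr8": 145, "chr9": 138, "chr10": 134,
    "chr11": 135, "chr12": 133, "chr13": 114, "chr14": 107, "chr15": 102,
    "chr16": 90, "chr17": 83, "chr18": 80, "chr19": 59, "chr20": 64,
    "chr21": 47, "chr22": 51,
}
_CHROMS = list(_CHROM_SIZES)
_CHROM_ORDER = {c: i for i, c in enumerate(_CHROMS)}

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}
_BASES = "ACGT"

#: fraction of single-base substitutions that are transitions (Ti/Tv ~ 2)
_TI_FRACTION = 2.0 / 3.0

TRUTH_COLUMNS = [
    "variant_key", "trio_id", "chrom", "pos", "ref", "alt", "variant_type",
    "parent_of_origin", "origin_category", "vaf_child_blood",
    "vaf_father_blood", "vaf_mother_blood", "vaf_father_sperm",
    "true_child_vaf", "hap_specific_vaf",
]


def variant_key(chrom: str, pos: int, ref: str, alt: str) -> str:
    return f"{chrom}-{pos}-{ref}-{alt}"


def _metadata_lines(config: SimulationConfig, what: str) -> list[str]:
    return [
        f"# dnmosaic v{__version__} {what}",
        f"# seed={config.seed} n_trios={config.n_trios} "
        f"mean_dnms_per_trio={config.mean_dnms_per_trio} "
        f"paternal_fraction={config.paternal_fraction} noise_vaf={config.noise_vaf}",
    ]


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    """Independent deterministic stream per output artifact."""
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream]))


def _draw_snv(rng: np.random.Generator) -> tuple[str, str]:
    ref = _BASES[rng.integers(4)]
    if rng.random() < _TI_FRACTION:
        return ref, _TRANSITION[ref]
    return ref, _TRANSVERSIONS[ref][rng.integers(2)]


def _draw_indel(rng: np.random.Generator) -> tuple[str, str]:
    anchor = _BASES[rng.integers(4)]
    insert = "".join(_BASES[i] for i in rng.integers(0, 4, size=rng.integers(1, 4)))
    if rng.random() < 0.5:
        return anchor, anchor + insert       # insertion
    return anchor + insert, anchor           # deletion


def simulate_truth(config: SimulationConfig) -> pd.DataFrame:
    """Draw the cohort truth table.

    Per trio the DNM count is Poisson(``mean_dnms_per_trio``); each DNM is
    paternal with probability ``paternal_fraction``; mosaic origin categories
    are injected per ``mosaic_spec`` with log-uniform VAFs.  For paternal blood
    mosaics the sperm VAF is the blood VAF times a factor in [1, 3] (shared
    mosaics are usually at least as abundant in sperm); sperm-confined mosaics
    are forced paternal; child postzygotic variants halve the constitutional
    VAF and set the haplotype-specific VAF below 1.
    """
    rng = _rng(config, 0)
    chrom_p = np.array([_CHROM_SIZES[c] for c in _CHROMS], dtype=float)
    chrom_p /= chrom_p.sum()
    rows = []
    for trio in range(1, config.n_trios + 1):
        n = int(rng.poisson(config.mean_dnms_per_trio))
        chroms = rng.choice(_CHROMS, size=n, p=chrom_p)
        positions = {}
        for i, chrom in enumerate(chroms):
            size = _CHROM_SIZES[chrom] * 1_000_000
            pos = int(rng.integers(10_000, size))
            while (chrom, pos) in positions:
                pos = int(rng.integers(10_000, size))
            positions[(chrom, pos)] = i
        keys = sorted(positions, key=lambda cp: (_CHROM_ORDER[cp[0]], cp[1]))
        is_indel = rng.random(n) < config.indel_fraction
        paternal = rng.random(n) < config.paternal_fraction
        trio_rows = []
        for i, (chrom, pos) in enumerate(keys):
            if is_indel[i]:
                ref, alt = _draw_indel(rng)
                vtype = "indel"
            else:
                ref, alt = _draw_snv(rng)
                vtype = "SNV"
            origin = "paternal" if paternal[i] else "maternal"
            trio_rows.append({
                "variant_key": variant_key(chrom, pos, ref, alt),
                "trio_id": f"trio{trio}", "chrom": chrom, "pos": pos,
                "ref": ref, "alt": alt, "variant_type": vtype,
                "parent_of_origin": origin, "origin_category": "one_off",
                "vaf_child_blood": 0.5, "vaf_father_blood": 0.0,
                "vaf_mother_blood": 0.0, "vaf_father_sperm": 0.0,
                "true_child_vaf": 0.5, "hap_specific_vaf": 1.0,
            })
        _inject_mosaics(trio_rows, config.mosaic_spec, rng)
        rows.extend(trio_rows)
    truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    return truth


def _inject_mosaics(trio_rows: list[dict], specs, rng: np.random.Generator) -> None:
    """Relabel a subset of a trio's one-off DNMs as mosaic categories in place."""
    available = list(range(len(trio_rows)))
    rng.shuffle(available)

    def take(pred):
        for j, idx in enumerate(available):
            if pred(trio_rows[idx]):
                return available.pop(j)
        return None

    for ms in specs:
        lo, hi = ms.count_range
        count = int(rng.integers(lo, hi + 1))
        for _ in range(count):
            vlo, vhi = ms.vaf_range
            vaf = float(np.exp(rng.uniform(np.log(vlo), np.log(vhi))))
            if ms.category == "pre_pgc_blood":
                idx = take(lambda r: True)
                if idx is None:
                    continue
                row = trio_rows[idx]
                row["origin_category"] = "pre_pgc_blood"
                if row["parent_of_origin"] == "paternal":
                    row["vaf_father_blood"] = vaf
                    row["vaf_father_sperm"] = min(vaf * rng.uniform(1.0, 3.0), 0.5)
                else:
                    row["vaf_mother_blood"] = vaf
            elif ms.category == "post_pgc_sperm_only":
                idx = take(lambda r: r["parent_of_origin"] == "paternal")
                if idx is None:
                    continue
                row = trio_rows[idx]
                row["origin_category"] = "post_pgc_sperm_only"
                row["vaf_father_sperm"] = vaf
            elif ms.category == "child_postzygotic":
                # postzygotic calling needs an SNV with a determined phase
                idx = take(lambda r: r["variant_type"] == "SNV")
                if idx is None:
                    continue
                row = trio_rows[idx]
                row["origin_category"] = "child_postzygotic"
                row["true_child_vaf"] = vaf
                row["hap_specific_vaf"] = min(2.0 * vaf, 1.0)


# ---------------------------------------------------------------------------
# trio VCF + PED


def trio_samples(trio_id: str) -> dict[str, str]:
    n = trio_id.removeprefix("trio")
    return {"child": f"child{n}", "father": f"father{n}", "mother": f"mother{n}"}


def simulate_trio_vcf(truth: pd.DataFrame, trio_id: str,
                      config: SimulationConfig) -> str:
    """Render one trio's VCF (v4.2 text) with GT/DP/GQ/AD per member.

    DNM records are drawn to pass the discovery filters (rejection sampling on
    depth, genotype quality and child VAF); inherited heterozygous variants
    are emitted ~1 kb from each DNM as phase-informative flankers that the
    genotype filter must reject.
    """
    rng = _rng(config, 1 + int(trio_id.removeprefix("trio")))
    sub = truth[truth.trio_id == trio_id]
    samples = trio_samples(trio_id)

    def draw_depth():
        while True:
            dp = int(rng.poisson(config.wgs_depth))
            if dp > 21:
                return dp

    def hom_ref(dp):
        return f"0/0:{dp}:{int(rng.integers(40, 61))}:{dp},0"

    def het(dp, p, min_vaf=0.0):
        for _ in range(100):
            alt = int(rng.binomial(dp, p))
            if 0 < alt and alt / dp > min_vaf:
                break
        else:
            alt = max(int(round(dp * p)), int(dp * min_vaf) + 1)
        return f"0/1:{dp}:{int(rng.integers(40, 61))}:{dp - alt},{alt}"

    records = []
    for row in sub.itertuples():
        dp_c, dp_f, dp_m = draw_depth(), draw_depth(), draw_depth()
        child = het(dp_c, row.true_child_vaf, min_vaf=0.26)
        records.append((row.chrom, row.pos, row.ref, row.alt,
                        child, hom_ref(dp_f), hom_ref(dp_m)))
        # inherited het flanker ~1 kb away: child + one parent 0/1
        fpos = row.pos + int(rng.integers(200, 1500))
        ref, alt = _draw_snv(rng)
        parent_het = rng.random() < 0.5
        dp1, dp2, dp3 = draw_depth(), draw_depth(), draw_depth()
        flank = (row.chrom, fpos, ref, alt, het(dp1, 0.5),
                 het(dp2, 0.5) if parent_het else hom_ref(dp2),
                 hom_ref(dp3) if parent_het else het(dp3, 0.5))
        records.append(flank)
    records.sort(key=lambda r: (_CHROM_ORDER[r[0]], r[1]))

    lines = [
        "##fileformat=VCFv4.2",
        f"##source=dnmosaic-{__version__}",
        f"##dnmosaic_seed={config.seed}",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
    ]
    lines += [f"##contig=<ID={c},length={_CHROM_SIZES[c] * 1_000_000}>"
              for c in _CHROMS]
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 f"{samples['child']}\t{samples['father']}\t{samples['mother']}")
    for chrom, pos, ref, alt, c, f, m in records:
        lines.append(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t50\tPASS\t.\t"
                     f"GT:DP:GQ:AD\t{c}\t{f}\t{m}")
    return "\n".join(lines) + "\n"


def simulate_ped(config: SimulationConfig) -> str:
    """Pedigree in 6-column PED format, one trio per family."""
    lines = []
    for t in range(1, config.n_trios + 1):
        s = trio_samples(f"trio{t}")
        lines.append(f"trio{t}\t{s['father']}\t0\t0\t1\t1")
        lines.append(f"trio{t}\t{s['mother']}\t0\t0\t2\t1")
        lines.append(f"trio{t}\t{s['child']}\t{s['father']}\t{s['mother']}\t0\t2")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# deep targeted counts


def _site_rate(base: float, config: SimulationConfig,
               rng: np.random.Generator) -> float:
    """Optionally gamma-perturb a per-site rate (CV = noise_dispersion)."""
    if config.noise_dispersion <= 0 or base <= 0:
        return base
    cv2 = config.noise_dispersion ** 2
    return float(base * rng.gamma(1.0 / cv2, cv2))


def _draw_total(mean: float, config: SimulationConfig,
                rng: np.random.Generator) -> int:
    if config.depth_dispersion > 0:
        cv2 = config.depth_dispersion ** 2
        mean = mean * rng.gamma(1.0 / cv2, cv2)
    return max(int(rng.poisson(mean)), 1)


def simulate_deep_counts(truth: pd.DataFrame,
                         config: SimulationConfig) -> pd.DataFrame:
    """Deduplicated deep-count table: every variant x every family x tissue
    x replicate.  Carrier tissues draw alt ~ Binomial(depth, VAF + noise);
    all other-family samples are pure noise and serve as pooled controls.
    A second independent replicate emulates the confirmation assay.
    """
    rng = _rng(config, 100)
    trios = [f"trio{t}" for t in range(1, config.n_trios + 1)]
    noise_site = {k: _site_rate(config.noise_vaf, config, rng)
                  for k in truth.variant_key}
    true_vaf = {}
    for row in truth.itertuples():
        true_vaf[(row.variant_key, row.trio_id)] = {
            "child_blood": row.true_child_vaf,
            "father_blood": row.vaf_father_blood,
            "mother_blood": row.vaf_mother_blood,
            "father_sperm": row.vaf_father_sperm,
        }
    rows = []
    for row in truth.itertuples():
        key = row.variant_key
        for trio in trios:
            vafs = true_vaf.get((key, trio), None)
            for tissue in TISSUES:
                member = {"child_blood": "child", "father_blood": "father",
                          "mother_blood": "mother", "father_sperm": "father"}[tissue]
                sample = f"{trio}_{member}_{'sperm' if tissue == 'father_sperm' else 'blood'}"
                v = vafs[tissue] if vafs else 0.0
                p = min(v + noise_site[key], 1.0)
                for replicate in ("primary", "confirmation"):
                    total = _draw_total(config.depths[tissue], config, rng)
                    alt = int(rng.binomial(total, p))
                    other = int(rng.poisson(total * config.noise_vaf * 0.5))
                    rows.append((key, trio, sample, tissue,
                                 total - alt, alt, other, replicate))
    return pd.DataFrame(rows, columns=[
        "variant_key", "trio", "sample", "tissue",
        "ref_count", "alt_count", "other_count", "replicate"])


# ---------------------------------------------------------------------------
# haplotype-tagged read evidence


def simulate_tagged_reads(truth: pd.DataFrame,
                          config: SimulationConfig) -> pd.DataFrame:
    """Long-read evidence per DNM: reads tagged paternal/maternal/untagged
    with a carries-alt flag.  On the origin haplotype the alt fraction is the
    haplotype-specific VAF (1 for constitutional variants, < 1 for child
    postzygotic mosaics); the other haplotype never carries the variant.
    """
    rng = _rng(config, 200)
    rows = []
    for row in truth.itertuples():
        n_reads = int(rng.poisson(config.longread_depth))
        for i in range(n_reads):
            u = rng.random()
            if u < config.untagged_read_fraction:
                hap = "untagged"
                carries = rng.random() < row.true_child_vaf
            else:
                hap = "paternal" if rng.random() < 0.5 else "maternal"
                if hap == row.parent_of_origin:
                    carries = rng.random() < row.hap_specific_vaf
                else:
                    carries = False
            rows.append((row.variant_key, f"{row.variant_key}:r{i}",
                         hap, int(carries)))
    return pd.DataFrame(rows, columns=[
        "variant_key", "read_id", "haplotype", "carries_alt"])


# ---------------------------------------------------------------------------
# parental WGS pileup (alt-read screen input)


def simulate_wgs_pileup(truth: pd.DataFrame,
                        config: SimulationConfig) -> pd.DataFrame:
    """Alt-read counts at DNM positions in the focal parents' standard-depth
    WGS.  Mosaic parents draw alt reads at their blood VAF; everyone sees the
    global noise floor, so sporadic false alt reads occur as in real pileups.
    """
    rng = _rng(config, 300)
    rows = []
    for row in truth.itertuples():
        for parent, vaf in (("father", row.vaf_father_blood),
                            ("mother", row.vaf_mother_blood)):
            depth = max(int(rng.poisson(config.wgs_depth)), 1)
            alt = int(rng.binomial(depth, min(vaf + config.noise_vaf, 1.0)))
            sample = trio_samples(row.trio_id)[parent]
            rows.append((row.variant_key, row.trio_id, sample, alt, depth))
    return pd.DataFrame(rows, columns=[
        "variant_key", "trio_id", "sample", "alt_count", "depth"])


# ---------------------------------------------------------------------------
# cohort bundle


@dataclass
class Cohort:
    """All synthetic artifacts for one simulated study."""

    config: SimulationConfig
    truth: pd.DataFrame
    vcfs: dict[str, str] = field(default_factory=dict)   # trio_id -> VCF text
    ped: str = ""
    counts: pd.DataFrame | None = None
    tagged_reads: pd.DataFrame | None = None
    wgs_pileup: pd.DataFrame | None = None


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Generate the complete synthetic study under one seed."""
    truth = simulate_truth(config)
    vcfs = {f"trio{t}": simulate_trio_vcf(truth, f"trio{t}", config)
            for t in range(1, config.n_trios + 1)}
    return Cohort(
        config=config,
        truth=truth,
        vcfs=vcfs,
        ped=simulate_ped(config),
        counts=simulate_deep_counts(truth, config),
        tagged_reads=simulate_tagged_reads(truth, config),
        wgs_pileup=simulate_wgs_pileup(truth, config),
    )


def write_cohort(cohort: Cohort, outdir: str | Path) -> dict[str, Path]:
    """Write every artifact as plain text; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    meta = _metadata_lines(cohort.config, "synthetic cohort")

    def write_tsv(name, df):
        p = outdir / name
        with open(p, "w") as fh:
            fh.write("\n".join(meta) + "\n")
            df.to_csv(fh, sep="\t", index=False)
        paths[name] = p

    write_tsv("truth.tsv", cohort.truth)
    write_tsv("deep_counts.tsv", cohort.counts)
    write_tsv("tagged_reads.tsv", cohort.tagged_reads)
    write_tsv("wgs_pileup.tsv", cohort.wgs_pileup)
    for trio_id, text in cohort.vcfs.items():
        p = outdir / f"{trio_id}.vcf"
        p.write_text(text)
        paths[f"{trio_id}.vcf"] = p
    p = outdir / "cohort.ped"
    p.write_text(cohort.ped)
    paths["cohort.ped"] = p
    return paths


def cohort_digest(cohort: Cohort) -> str:
    """SHA-256 over all rendered artifacts; equal seeds give equal digests."""
    h = hashlib.sha256()
    for df in (cohort.truth, cohort.counts, cohort.tagged_reads,
               cohort.wgs_pileup):
        h.update(df.to_csv(sep="\t", index=False).encode())
    for trio_id in sorted(cohort.vcfs):
        h.update(cohort.vcfs[trio_id].encode())
    h.update(cohort.ped.encode())
    return h.hexdigest()
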