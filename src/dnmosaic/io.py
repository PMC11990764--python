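"""Readers and writers for the pipeline's interchange formats.

VCF parsing goes through pysam; tab-separated tables carry a ``#``-prefixed
metadata block (tool version, seed, thresholds) that readers skip.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterator

import pandas as pd
import pysam

from . import __version__
from .discovery import MEMBERS, MemberGenotype, TrioGenotypeRecord

REQUIRED_FORMATS = ("GT", "DP", "GQ", "AD")


class VcfContractError(ValueError):
    """The VCF does not satisfy the pipeline's input contract."""


def read_ped(path: str | Path) -> dict[str, dict[str, str]]:
    """Parse a 6-column PED into {family: {child, father, mother}}.

    The child is the individual whose father and mother columns are set.
    """
    families: dict[str, dict[str, str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fam, iid, father, mother = line.split("\t")[:4]
            entry = families.setdefault(fam, {})
            if father != "0" and mother != "0":
                entry["child"] = iid
                entry["father"] = father
                entry["mother"] = mother
    for fam, entry in families.items():
        missing = [m for m in MEMBERS if m not in entry]
        if missing:
            raise ValueError(f"pedigree family {fam!r} lacks {missing}")
    return families


def _member_genotype(sample) -> MemberGenotype:
    gt = sample.get("GT")
    if gt is not None and any(a is None for a in gt):
        gt = None
    ad = sample.get("AD")
    if ad is not None:
        ad = tuple(int(a) for a in ad if a is not None)
    return MemberGenotype(
        genotype=tuple(gt) if gt is not None else None,
        dp=sample.get("DP"),
        gq=sample.get("GQ"),
        ad=ad,
    )


def read_trio_vcf(path: str | Path, trio: dict[str, str]
                  ) -> Iterator[TrioGenotypeRecord | None]:
    """Stream biallelic trio records from a VCF.

    ``trio`` maps child/father/mother to the VCF sample names.  Multi-allelic
    sites yield None (callers count and skip them).  Missing FORMAT
    declarations and sample mismatches are fatal up front.
    """
    vf = pysam.VariantFile(str(path))
    declared = set(vf.header.formats.keys())
    for fmt in REQUIRED_FORMATS:
        if fmt not in declared:
            raise VcfContractError(f"VCF lacks required FORMAT field {fmt}")
    vcf_samples = list(vf.header.samples)
    wanted = [trio[m] for m in MEMBERS]
    missing = [s for s in wanted if s not in vcf_samples]
    if missing:
        raise VcfContractError(
            f"pedigree samples {missing} absent from VCF samples {vcf_samples}")
    for rec in vf:
        if rec.alts is None or len(rec.alts) != 1:
            yield None
            continue
        members = {m: _member_genotype(rec.samples[trio[m]]) for m in MEMBERS}
        yield TrioGenotypeRecord(chrom=rec.chrom, pos=rec.pos, ref=rec.ref,
                                 alt=rec.alts[0], members=members)


def metadata_block(seed: int, thresholds: dict | None = None) -> str:
    lines = [f"# dnmosaic v{__version__}", f"# seed={seed}"]
    if thresholds:
        lines.append("# thresholds=" + json.dumps(thresholds, sort_keys=True))
    return "\n".join(lines) + "\n"


def write_tsv(df: pd.DataFrame, path: str | Path, seed: int = 0,
              thresholds: dict | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(metadata_block(seed, thresholds))
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_json(obj: dict, path: str | Path, seed: int = 0,
               thresholds: dict | None = None) -> None:
    payload = {"tool": f"dnmosaic v{__version__}", "seed": seed}
    if thresholds:
        payload["thresholds"] = thresholds
    payload.update(obj)
    Path(path).write_text(json.dumps(payload, indent=2, default=_jsonable))


def _jsonable(x):
    try:
        return x.item()
    except AttributeError:
        return str(x)
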