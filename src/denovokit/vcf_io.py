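"""Trio VCF input/output for candidate and validated de novo SNVs.

One file per child trio, with CHILD/FATHER/MOTHER sample columns carrying
DP, AD, GQ and SAC-style strand counts; pysam handles the format itself.
The tab-delimited candidate table remains the primary interchange format —
these helpers exist so call sets can round-trip through standard tooling.
"""

from __future__ import annotations

import pandas as pd
import pysam

from .dnmfilter import CANDIDATE_METRICS

_FORMAT_LINES = [
    ('FORMAT', 'DP', '1', 'Integer', 'Read depth'),
    ('FORMAT', 'AD', 'R', 'Integer', 'Allelic depths (ref, alt)'),
    ('FORMAT', 'GQ', '1', 'Integer', 'Genotype quality'),
    ('FORMAT', 'SAC', '.', 'Integer', 'Strand alt counts (fwd, rev)'),
]


def write_trio_vcf(variants: pd.DataFrame, path, contig_lengths: dict[str, int] | None = None) -> None:
    """Write one child's candidate/validated SNVs as a trio VCF.

    ``variants`` must contain a single child_id; samples are written in the
    order CHILD, FATHER, MOTHER.
    """
    children = variants["child_id"].unique()
    if len(children) != 1:
        raise ValueError(f"write_trio_vcf expects exactly one child, got {len(children)}")
    header = pysam.VariantHeader()
    header.add_meta("source", "denovokit")
    for key, i, num, typ, desc in _FORMAT_LINES:
        header.add_meta(key, items=[("ID", i), ("Number", num), ("Type", typ), ("Description", desc)])
    contigs = contig_lengths or {
        c: int(variants.loc[variants["chrom"] == c, "pos"].max()) + 1000
        for c in sorted(variants["chrom"].unique())
    }
    for c, ln in contigs.items():
        header.contigs.add(c, length=ln)
    header.add_meta("child_id", str(children[0]))
    for s in ("CHILD", "FATHER", "MOTHER"):
        header.add_sample(s)

    with pysam.VariantFile(str(path), "w", header=header) as out:
        for r in variants.sort_values(["chrom", "pos"]).itertuples(index=False):
            rec = out.new_record(
                contig=r.chrom, start=int(r.pos) - 1, stop=int(r.pos),
                alleles=(r.ref, r.alt), id=".",
            )
            rec.samples["CHILD"]["DP"] = int(r.child_depth)
            rec.samples["CHILD"]["AD"] = (int(r.child_depth - r.child_alt), int(r.child_alt))
            rec.samples["CHILD"]["GQ"] = int(r.child_gq)
            rec.samples["CHILD"]["SAC"] = (int(r.child_alt_fwd), int(r.child_alt_rev))
            for sample, dp, ad, gq in (
                ("FATHER", r.father_depth, r.father_alt, r.father_gq),
                ("MOTHER", r.mother_depth, r.mother_alt, r.mother_gq),
            ):
                rec.samples[sample]["DP"] = int(dp)
                rec.samples[sample]["AD"] = (int(dp - ad), int(ad))
                rec.samples[sample]["GQ"] = int(gq)
                rec.samples[sample]["SAC"] = (0, 0)
            out.write(rec)


def read_trio_vcf(path, child_id: str | None = None, family_id: str = "") -> pd.DataFrame:
    """Read a trio VCF back into the candidate-table schema."""
    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        meta_child = next(
            (rec.value for rec in vcf.header.records if rec.key == "child_id"), None
        )
        child = child_id or meta_child or "CHILD"
        for rec in vcf:
            c = rec.samples["CHILD"]
            f = rec.samples["FATHER"]
            m = rec.samples["MOTHER"]
            sac = c["SAC"]
            rows.append(
                {
                    "chrom": rec.contig,
                    "pos": rec.pos,
                    "ref": rec.ref,
                    "alt": rec.alts[0],
                    "child_id": child,
                    "family_id": family_id,
                    "callers": "A",
                    "child_depth": c["DP"], "child_alt": c["AD"][1],
                    "child_alt_fwd": sac[0], "child_alt_rev": sac[1],
                    "father_depth": f["DP"], "father_alt": f["AD"][1],
                    "mother_depth": m["DP"], "mother_alt": m["AD"][1],
                    "child_gq": c["GQ"], "father_gq": f["GQ"], "mother_gq": m["GQ"],
                }
            )
    cols = ["chrom", "pos", "ref", "alt", "child_id", "family_id", "callers"] + CANDIDATE_METRICS
    return pd.DataFrame(rows, columns=cols)
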