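"""Build merged LD blocks around the genome-wide significant GWAS SNPs.

Filters the GWAS table at P < 5e-8, picks flanking panel proxies for each
hit, spans each block over the panel variants with r2 >= 0.8 to either proxy
inside a 500-kb window, and merges overlapping blocks across population
groups.
"""

from pathlib import Path

from cre_enrich import io
from cre_enrich.ld import LdParams, filter_gwas
from cre_enrich.pipeline import stage_ld_blocks

RUN = Path(__file__).resolve().parent.parent / "results" / "run"


def main() -> None:
    params = LdParams()
    snps = io.read_snp_table(RUN / "gwas.tsv")
    significant = filter_gwas(snps, params.p_threshold)
    blocks = stage_ld_blocks(
        RUN / "gwas.tsv",
        RUN / "panel.vcf",
        params,
        RUN / "blocks.bed",
        RUN / "blocks_provenance.tsv",
    )
    total = sum(b.interval.length for b in blocks)
    print(f"{len(significant)} of {len(snps)} SNPs reach P < {params.p_threshold:g}")
    print(f"{len(blocks)} merged LD blocks covering {total} bp "
          f"-> {RUN / 'blocks.bed'}")


if __name__ == "__main__":
    main()
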