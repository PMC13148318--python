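"""Classify cross-species conservation of DARs and contrast tissues.

Projection scores are cut at >0.98 (direct) and >0.84 (indirect); a DAR is
functionally conserved when its conserved projection overlaps a DAR in the
other species, regardless of cell type. Reports per-direction class
proportions, functional-conservation rates, identity retention among
conserved DARs, and the ectoderm/mesenchyme rate ratio with a Fisher exact
p-value.
"""

from pathlib import Path

from cre_enrich.pipeline import stage_conserve

RUN = Path(__file__).resolve().parent.parent / "results" / "run"


def main() -> None:
    summary = stage_conserve(RUN)
    print(summary.to_string(index=False))
    print(f"-> {RUN / 'conservation_summary.tsv'}")


if __name__ == "__main__":
    main()
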