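"""Tabulate amplification/sequencing success of the eight candidate loci.

The packaged pilot screen (23 specimens of eight endemic Vietnamese
Paphiopedilum species) shows why only ITS, matK, trnL, rpoB and rpoC1
proceed to sequence analysis: the nuclear ACO/LEAFY primers amplify poorly
(31.25% at best) and trnH-psbA amplifies well (82.61%) but sequences badly
(31.58%).
"""

from pathlib import Path

from paphbarcode.datasets import pilot_screening_status
from paphbarcode.resolution import status_rates, write_status_rates_tsv

OUT = Path(__file__).resolve().parent.parent / "results"


def main():
    OUT.mkdir(exist_ok=True)
    rates = status_rates(pilot_screening_status())
    write_status_rates_tsv(rates, OUT / "screening_rates.tsv")
    print(f"{'assay':<12} {'attempted':>9} {'amplified':>9} {'amp %':>8} {'seq %':>8}")
    for r in rates.values():
        amp = "-" if r.amplification_rate_pct is None else f"{r.amplification_rate_pct:.2f}"
        seq = "-" if r.sequencing_rate_pct is None else f"{r.sequencing_rate_pct:.2f}"
        print(f"{r.assay:<12} {r.attempted:>9} {r.amplified:>9} {amp:>8} {seq:>8}")
    print(f"\nwrote {OUT / 'screening_rates.tsv'}")


if __name__ == "__main__":
    main()
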