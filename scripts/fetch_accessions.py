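"""Optional helper: download the study's deposited cyt-b sequences.

Fetches GenBank accessions JF489575-JF489887 via NCBI E-utilities (network
required; nothing in the package or test suite depends on this data) and
writes them as a FASTA file for use with the pipeline CLI.

Usage:  python scripts/fetch_accessions.py --out data/cytb_accessions.fasta
"""

import argparse
from pathlib import Path

from Bio import Entrez, SeqIO

FIRST, LAST = 489575, 489887


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", type=Path, required=True)
    ap.add_argument("--email", default="anonymous@example.org",
                    help="contact email NCBI asks clients to send")
    args = ap.parse_args()
    Entrez.email = args.email
    ids = [f"JF{i}" for i in range(FIRST, LAST + 1)]
    handle = Entrez.efetch(db="nucleotide", id=",".join(ids), rettype="fasta", retmode="text")
    records = list(SeqIO.parse(handle, "fasta"))
    args.out.parent.mkdir(parents=True, exist_ok=True)
    SeqIO.write(records, str(args.out), "fasta")
    print(f"wrote {len(records)} records to {args.out}")
    print("Note: sequences are unaligned; align them (e.g. with mafft) and trim "
          "to the shared region before running the pipeline.")


if __name__ == "__main__":
    main()
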