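"""Optionally fetch the six bovine-milk reference proteins from UniProt.

Requires network access; the core library never performs network I/O.
Writes milk_proteins.fasta in the current directory, ready for
``acescreen screen --proteins milk_proteins.fasta ...``.
"""

import urllib.request

ACCESSIONS = ["P02666", "P02668", "P02662", "P02663", "P02754", "P00711"]

chunks = []
for acc in ACCESSIONS:
    url = f"https://rest.uniprot.org/uniprotkb/{acc}.fasta"
    with urllib.request.urlopen(url, timeout=30) as resp:
        chunks.append(resp.read().decode())
    print(f"fetched {acc}")

with open("milk_proteins.fasta", "w", encoding="utf-8") as fh:
    fh.write("".join(chunks))
print("wrote milk_proteins.fasta")
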