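#!/usr/bin/env python
"""One-time fetch of the Ensembl GRCm38 fixtures used by the external-data
tests (network required; run from the repository root).

Writes into tests/data/external/:

  classical_markers.fa   peptide sequences of the osteoblast markers
                         RUNX2 (Runx2), OSX (Sp7), COL1A1 (Col1a1) and
                         OCN (Bglap), one documented isoform each
  panel_proteins.fa      peptides for the western-panel proteins COL1A1,
                         ATF4 and EIF4EBP1
  Mus_musculus.GRCm38.pep.all.fa
                         the full GRCm38 peptide set (~50 MB uncompressed)
  go_0001649_genes.txt   Ensembl gene stable IDs annotated to GO:0001649
                         (osteoblast differentiation), one per line
  provenance.json        release numbers, dates, chosen isoforms

Isoform choice: for each marker the script fetches every translated isoform
of the gene and keeps the one whose proline fraction matches the published
value at 3 d.p. (falling back to the longest isoform, recorded as such in
provenance.json), because the original analysis does not name the isoforms
it used.
"""

import gzip
import io
import json
import shutil
import sys
import urllib.parse
import urllib.request
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from prodemand import composition  # noqa: E402

OUT = Path(__file__).resolve().parents[1] / "tests" / "data" / "external"
REST_MAIN = "https://rest.ensembl.org"
# GRCm38 peptide set: release 102 is the last mouse GRCm38 release
PEP_URL = (
    "http://ftp.ensembl.org/pub/release-102/fasta/mus_musculus/pep/"
    "Mus_musculus.GRCm38.pep.all.fa.gz"
)
BIOMART_URL = "http://nov2020.archive.ensembl.org/biomart/martservice"

MARKERS = {  # display name -> (mouse gene symbol, published Pro fraction)
    "RUNX2": ("Runx2", 0.105),
    "OSX": ("Sp7", 0.133),
    "COL1A1": ("Col1a1", 0.190),
    "OCN": ("Bglap", 0.074),
}
PANEL = {"COL1A1": ("Col1a1", 0.191), "ATF4": ("Atf4", 0.106),
         "EIF4EBP1": ("Eif4ebp1", 0.137)}

BIOMART_QUERY = """<?xml version="1.0" encoding="UTF-8"?>
<!DOCTYPE Query>
<Query virtualSchemaName="default" formatter="TSV" header="0" uniqueRows="1">
  <Dataset name="mmusculus_gene_ensembl">
    <Filter name="go_parent_term" value="GO:0001649"/>
    <Attribute name="ensembl_gene_id"/>
  </Dataset>
</Query>
"""


def get_json(url: str):
    req = urllib.request.Request(url, headers={"Content-Type": "application/json"})
    with urllib.request.urlopen(req, timeout=60) as resp:
        return json.load(resp)


def gene_isoforms(symbol: str) -> list[dict]:
    """All translated isoforms of a mouse gene symbol: [{protein_id,
    transcript_id, gene_id, seq}]."""
    lookup = get_json(
        f"{REST_MAIN}/lookup/symbol/mus_musculus/"
        f"{urllib.parse.quote(symbol)}?expand=1;content-type=application/json"
    )
    isoforms = []
    for tr in lookup.get("Transcript", []):
        translation = tr.get("Translation")
        if not translation:
            continue
        seq = get_json(
            f"{REST_MAIN}/sequence/id/{translation['id']}"
            "?type=protein;content-type=application/json"
        )["seq"]
        isoforms.append(
            {
                "protein_id": translation["id"],
                "transcript_id": tr["id"],
                "gene_id": lookup["id"],
                "seq": seq,
            }
        )
    if not isoforms:
        raise RuntimeError(f"no translated isoforms found for {symbol}")
    return isoforms


def choose_isoform(isoforms: list[dict], target_pro: float) -> tuple[dict, str]:
    for iso in sorted(isoforms, key=lambda i: -len(i["seq"])):
        pro = composition(iso["seq"]).fractions["P"]
        if round(pro, 3) == round(target_pro, 3):
            return iso, "matched published Pro fraction"
    longest = max(isoforms, key=lambda i: len(i["seq"]))
    return longest, "fallback: longest isoform (no isoform matched at 3 d.p.)"


def write_fasta(path: Path, chosen: dict[str, dict]) -> None:
    with open(path, "w") as fh:
        for display, iso in chosen.items():
            fh.write(
                f">{iso['protein_id']} pep gene:{iso['gene_id']} "
                f"transcript:{iso['transcript_id']} gene_symbol:{display}\n"
            )
            for i in range(0, len(iso["seq"]), 60):
                fh.write(iso["seq"][i : i + 60] + "\n")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    provenance: dict = {"rest_host": REST_MAIN, "pep_url": PEP_URL, "isoforms": {}}

    for name, target, group in [("classical_markers.fa", MARKERS, "markers"),
                                ("panel_proteins.fa", PANEL, "panel")]:
        chosen = {}
        for display, (symbol, pro) in target.items():
            iso, how = choose_isoform(gene_isoforms(symbol), pro)
            chosen[display] = iso
            provenance["isoforms"][display] = {
                "group": group,
                "symbol": symbol,
                "protein_id": iso["protein_id"],
                "selection": how,
            }
            print(f"{display}: {iso['protein_id']} ({how})")
        write_fasta(OUT / name, chosen)

    print("downloading full GRCm38 peptide set (~15 MB gz) ...")
    with urllib.request.urlopen(PEP_URL, timeout=600) as resp:
        gz = io.BytesIO(resp.read())
    with gzip.open(gz) as src, open(OUT / "Mus_musculus.GRCm38.pep.all.fa", "wb") as dst:
        shutil.copyfileobj(src, dst)

    print("querying BioMart for GO:0001649 gene membership ...")
    data = urllib.parse.urlencode({"query": BIOMART_QUERY}).encode()
    with urllib.request.urlopen(BIOMART_URL, data=data, timeout=300) as resp:
        genes = sorted(
            {line.strip() for line in resp.read().decode().splitlines() if line.strip()}
        )
    (OUT / "go_0001649_genes.txt").write_text("\n".join(genes) + "\n")
    provenance["n_go_genes"] = len(genes)

    (OUT / "provenance.json").write_text(json.dumps(provenance, indent=2) + "\n")
    print(f"fixtures written to {OUT}")


if __name__ == "__main__":
    main()
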