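"""Regenerate the frozen catalog network fixtures.

For each of the 17 canonical simplest cluster sets, run the bounded
minimal-reticulation search and freeze the resulting network as eNewick
under src/dcnet/data/.  Any softwired-correct network is a valid fixture
(network transfer between isomorphic sets does not depend on which
representative is stored); the search is deterministic, so reruns
reproduce identical files.

Usage: python scripts/regenerate_catalog.py
"""

import pathlib
import sys

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

from dcnet.catalog import entries, verify_catalog
from dcnet.construct import fallback_search
from dcnet.enewick import write_enewick
from dcnet.io import write_clusters
from dcnet.network import reticulation_number, represents_all_softwired

DATA = pathlib.Path(__file__).resolve().parents[1] / "src" / "dcnet" / "data"


def main():
    DATA.mkdir(parents=True, exist_ok=True)
    for e in entries():
        net = fallback_search(e.clusters, max_r=6, trial_cap=60_000)
        assert represents_all_softwired(net, e.clusters) is not None
        r = reticulation_number(net)
        text = write_enewick(net)
        (DATA / f"{e.name}.enewick").write_text(text + "\n")
        write_clusters(e.clusters, DATA / f"{e.name}.clusters")
        print(f"{e.name}: r={r} {text}")
    report = verify_catalog()
    print("catalog verification:", "ok" if report.ok else f"FAILED {report.failures()}")
    return 0 if report.ok else 1


if __name__ == "__main__":
    raise SystemExit(main())
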