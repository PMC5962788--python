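import random

import pytest

from sigscan.seq_io import Alignment, GroupManifest


@pytest.fixture
def manifest_5in_4out() -> GroupManifest:
    """Five in-group taxa (class In) and four out-group taxa, with a
    nested two-member genus inside the in-group."""
    entries = {f"A{i}": {"class": "In", "genus": "unassigned"} for i in range(1, 6)}
    entries["A1"]["genus"] = "Gsub"
    entries["A2"]["genus"] = "Gsub"
    entries.update({f"O{i}": {"class": "Out"} for i in range(1, 5)})
    return GroupManifest(entries).with_ingroup("class", "In")


def random_alignment_and_manifest(rng: random.Random, max_rows: int = 6,
                                  max_cols: int = 12):
    """Small random gapped alignment with a matching 2-clade manifest.

    Rows are split between an in-group and an out-group (at least one row
    each; classification needs both sides to say anything exclusive).
    """
    n_rows = rng.randint(2, max_rows)
    n_cols = rng.randint(1, max_cols)
    n_in = rng.randint(1, n_rows - 1)
    taxa = [f"r{i}" for i in range(n_rows)]
    rows = []
    for t in taxa:
        seq = "".join(rng.choice("ACDE-") for _ in range(n_cols))
        rows.append((t, seq))
    # ensure no all-gap row (Alignment drops all-gap columns, so a row of
    # gaps only matters if another row has residues there; keep it simple)
    rows = [
        (t, s if set(s) != {"-"} else "A" + s[1:]) for t, s in rows
    ]
    try:
        aln = Alignment(rows)
    except ValueError:
        return None
    entries = {t: {"class": "In" if i < n_in else "Out"} for i, t in enumerate(taxa)}
    man = GroupManifest(entries).with_ingroup("class", "In")
    return aln, man
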