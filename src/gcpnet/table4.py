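"""Published benchmark of intermediate-node z-scores.

Twenty intermediate nodes of an autoimmune seed subnetwork, each with its
background link count n, distinct-seed link count k, the shared subnetwork
link count K = 60 and background link count N = 11429, and the published
z-score.  The table serves as the numerical validation gate for the
binomial-proportion z reconstruction: the recomputed z must agree with
every published value within +/-0.005.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

TABLE4_K = 60
TABLE4_N = 11429


@dataclass(frozen=True)
class Table4Row:
    gene: str
    n: int            # "Link": background degree
    N: int            # "Link in background"
    k: int            # "Links to seed"
    K: int            # "Links in subnetwork"
    z_printed: float  # published z-score


def _parse_float(text: str) -> float:
    """Parse a float in either period- or comma-decimal dialect."""
    text = text.strip()
    if "," in text and "." not in text:
        text = text.replace(",", ".")
    return float(text)


def load_table4(path: str | Path | None = None) -> list[Table4Row]:
    """Load the benchmark rows (shipped fixture unless a path is given)."""
    if path is None:
        source = resources.files("gcpnet.data").joinpath("table4.tsv")
        with resources.as_file(source) as p:
            df = pd.read_csv(p, sep="\t", dtype=str)
    else:
        df = pd.read_csv(path, sep="\t", dtype=str)
    rows = [
        Table4Row(
            gene=r["Gene name"],
            n=int(r["Link"]),
            N=int(r["Link in background"]),
            k=int(r["Links to seed"]),
            K=int(r["Links in subnetwork"]),
            z_printed=_parse_float(r["z-score"]),
        )
        for _, r in df.iterrows()
    ]
    return rows


def table4_fixture() -> list[tuple[str, int, int, int, int, float]]:
    """Rows as ``(gene, n, N, k, K, printed z)`` tuples."""
    return [(r.gene, r.n, r.N, r.k, r.K, r.z_printed) for r in load_table4()]
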