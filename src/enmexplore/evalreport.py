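"""Evaluation of a finished run against an optional bound reference.

Evaluation is strictly read-only: the metrics computed here (RMSD to the
bound structure, counts within a reporting threshold, compactness
tables) never feed back into the search, which keeps the generation
procedure unbiased. The 3 Angstrom "close to bound" threshold is a
reporting convention, exposed as an argument.
"""

from __future__ import annotations

import dataclasses
import io
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .explore import LineageTree
from .structio import Structure, rmsd_ca

__all__ = ["EvalRow", "evaluate", "summarize", "rg_rmsd_table", "CLOSE_THRESHOLD"]

CLOSE_THRESHOLD = 3.0  # A, reporting threshold for "close to bound"


@dataclasses.dataclass
class EvalRow:
    conformer_id: str
    generation: int
    rg: float
    rg_per_chain: dict[str, float]
    rmsd_to_holo: float
    rmsd_per_chain: dict[str, float]
    energy: float
    below_3A: bool
    in_rg_filter: bool


def evaluate(
    tree: LineageTree,
    holo: Structure,
    threshold: float = CLOSE_THRESHOLD,
    receptor_chains: Sequence[str] | None = None,
) -> list[EvalRow]:
    """Per-conformer comparison of a lineage tree against a bound reference.

    Multimers additionally get per-chain RMSDs, each computed after
    superposing on that chain alone. ``receptor_chains`` restricts the
    comparison (e.g. to exclude a ligand chain in a re-seeded run).
    """
    apo_rg = tree.nodes[tree.root_id].rg
    chains = holo.chain_ids
    rows: list[EvalRow] = []
    for conf in tree.conformers():
        mobile = conf.structure
        if receptor_chains is not None:
            mobile = mobile.subset_chains(receptor_chains)
        r = rmsd_ca(mobile, holo)
        per_chain = (
            {ch: rmsd_ca(mobile, holo, chains=[ch]) for ch in chains}
            if len(chains) > 1
            else {}
        )
        rows.append(
            EvalRow(
                conformer_id=conf.id,
                generation=conf.generation,
                rg=conf.rg,
                rg_per_chain=dict(conf.rg_per_chain),
                rmsd_to_holo=r,
                rmsd_per_chain=per_chain,
                energy=conf.energy,
                below_3A=r < threshold,
                in_rg_filter=conf.rg <= apo_rg,
            )
        )
    return rows


def summarize(rows: Sequence[EvalRow]) -> dict:
    """Run-level summary: totals, filtered counts, minimum RMSD."""
    if not rows:
        raise ValueError("no rows to summarize")
    rmsds = np.array([r.rmsd_to_holo for r in rows])
    assert float(rmsds.min()) == min(r.rmsd_to_holo for r in rows)
    return {
        "n_conformers": len(rows),
        "n_in_rg_filter": sum(r.in_rg_filter for r in rows),
        "n_below_threshold": sum(r.below_3A for r in rows),
        "min_rmsd": float(rmsds.min()),
        "min_rmsd_id": rows[int(np.argmin(rmsds))].conformer_id,
    }


def rg_rmsd_table(
    rows: Sequence[EvalRow],
    apo_rg: float,
    holo_rg: float,
    path: str | Path | None = None,
) -> str:
    """Compactness-vs-RMSD table for external plotting.

    Two reference comment lines carry the start-state and bound-state
    radii of gyration, followed by a header and one TSV row per
    conformer (generation, rg, rmsd_to_holo).
    """
    if not rows:
        raise ValueError("no rows to tabulate")
    df = pd.DataFrame(
        {
            "generation": [r.generation for r in rows],
            "rg": [round(r.rg, 4) for r in rows],
            "rmsd_to_holo": [round(r.rmsd_to_holo, 4) for r in rows],
        }
    )
    buf = io.StringIO()
    buf.write(f"# apo_rg\t{apo_rg:.4f}\n")
    buf.write(f"# holo_rg\t{holo_rg:.4f}\n")
    df.to_csv(buf, sep="\t", index=False)
    text = buf.getvalue()
    if path is not None:
        Path(path).write_text(text)
    return text
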