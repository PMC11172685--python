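"""Bundled reference data: published Tier-II hit tables.

Two small score tables ship with the package, transcribed from the
published screen against the SHP2 junction pocket:

* ``tier2_tba_hits`` — the 18 affinity-selected (t-BA) candidates, with
  best-pose affinities against the SHP099-bound wild-type and E76K
  receptors;
* ``tier2_hvi_hits`` — the 21 manually curated (h-VI) candidates.

The two id sets are disjoint; their union of 39 compounds is the Tier-III
input set.
"""

from __future__ import annotations

from importlib import resources

from .structio import ScoreTable, read_score_table

__all__ = ["load_tba_hits", "load_hvi_hits", "RECEPTOR_WT", "RECEPTOR_MT"]

RECEPTOR_WT = "wtSHP2-b"
RECEPTOR_MT = "mtSHP2-b"


def _load(name: str) -> ScoreTable:
    ref = resources.files("allokit.data").joinpath(name)
    with resources.as_file(ref) as path:
        return read_score_table(path)


def load_tba_hits() -> ScoreTable:
    """Affinity-selected (t-BA) Tier-II hit table (18 compounds x 2 receptors)."""
    return _load("tier2_tba_hits.csv")


def load_hvi_hits() -> ScoreTable:
    """Manually curated (h-VI) Tier-II hit table (21 compounds x 2 receptors)."""
    return _load("tier2_hvi_hits.csv")
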