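"""The packaged TME panel: a synthetic stand-in gene panel.

The shipped GMT (``data/tme_panel_synthetic.gmt``) mirrors the structure of
a NanoString-style TME panel — 25 immune-associated "A" genes (direction +1)
and 19 stromal/immune-exclusion "B" genes (direction -1) — but its exact
gene membership is a synthetic reconstruction from field-typical immune and
stromal markers (it includes the stromal-activation genes FAP, MIR100HG,
SYNPO and TGFB1I1); it is NOT a published signature.  The 10 housekeeping
genes and 7 checkpoint genes below are panel metadata used by the
normalization and fixture code.
"""

from __future__ import annotations

from importlib import resources

from .io import SignatureCollection, read_gmt

HOUSEKEEPING_GENES: list[str] = [
    "ACTB", "ABCF1", "B2M", "G6PD", "GAPDH",
    "GUSB", "PGK1", "RPLPO", "TFRC", "TUBB",
]

CHECKPOINT_GENES: list[str] = [
    "CD274", "PDCD1LG2", "LAG3", "CTLA4", "TIGIT", "HAVCR2", "PDCD1",
]

PANEL_RESOURCE = "tme_panel_synthetic.gmt"


def load_panel() -> SignatureCollection:
    """Load the packaged synthetic A/B signature panel (25 + 19 genes)."""
    path = resources.files("tmescore.data") / PANEL_RESOURCE
    with resources.as_file(path) as p:
        return read_gmt(p)
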