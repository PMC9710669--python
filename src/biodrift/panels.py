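"""Built-in known biomarker panels.

Only the three-marker panel M3 — the estrogen receptor gene, the HER2
receptor gene and the Ki-67 proliferation marker gene — ships with the
package; membership of the larger commercial panels (PAM50, EndoPredict,
OncotypeDX) is not bundled and is supplied by the user as a plain-text gene
list, one identifier per line.
"""

from __future__ import annotations

from pathlib import Path

from .features import FeatureSet

M3 = FeatureSet(["ESR1", "ERBB2", "MKI67"], origin="known_panel")

BUILTIN = {"m3": M3, "empty": FeatureSet(origin="known_panel")}


def load_panel(spec: str) -> FeatureSet:
    """Resolve a panel name: a builtin key ('m3', 'empty') or a file path."""
    key = spec.lower()
    if key in BUILTIN:
        return BUILTIN[key]
    path = Path(spec)
    if not path.exists():
        raise FileNotFoundError(
            f"panel {spec!r} is neither builtin ({sorted(BUILTIN)}) nor a file")
    genes = [ln.strip() for ln in path.read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    return FeatureSet(genes, origin="known_panel")
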