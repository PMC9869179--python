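"""Packaged gene-signature fixtures.

The single shipped fixture, ``conserved48``, is the consensus list of genes
bound by HIF and upregulated by hypoxia in all six assayed cancer cell
lines.  The fixture is immutable: every load returns an equal value.
"""

from __future__ import annotations

import json
from importlib import resources

from .types import SignatureSet

__all__ = ["available_signatures", "load_signature"]

_FIXTURES = {"conserved48": "conserved48.json"}


def available_signatures() -> list[str]:
    """Names accepted by :func:`load_signature`."""
    return sorted(_FIXTURES)


def load_signature(name: str = "conserved48") -> SignatureSet:
    """Load a packaged signature fixture by name.

    Raises ``LookupError`` listing the available fixtures for unknown names.
    """
    if name not in _FIXTURES:
        raise LookupError(
            f"unknown signature {name!r}; available fixtures: {available_signatures()}"
        )
    payload = json.loads(
        resources.files("hifmeta.data").joinpath(_FIXTURES[name]).read_text()
    )
    genes = tuple(payload["genes"])
    membership = {
        g: {
            sig: bool(payload.get("published_membership", {}).get(g, {}).get(sig, False))
            for sig in payload.get("published_signatures", [])
        }
        for g in genes
    }
    return SignatureSet(
        genes=genes,
        provenance={},
        published_membership=membership,
        note=payload.get("membership_note", ""),
    )
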