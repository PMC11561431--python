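"""Shared figure-saving helper."""

from __future__ import annotations

from pathlib import Path
from typing import Union


def save_figure(fig, path: Union[str, Path]) -> Path:
    """Save without volatile metadata so identical input gives identical bytes."""
    import matplotlib

    path = Path(path)
    kwargs = {}
    if path.suffix.lower() == ".svg":
        kwargs["metadata"] = {"Date": None}  # no timestamp
    with matplotlib.rc_context({"svg.hashsalt": "behavdet"}):  # stable ids
        fig.savefig(path, **kwargs)
    return path
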