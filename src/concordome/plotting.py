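"""Optional matplotlib figures for visual inspection.

These are convenience hooks, not part of the tested analysis contract:
the serialized TSV/JSON reports are the authoritative output.
"""

from __future__ import annotations

from .io_tables import fmt_threshold
from .portrait import CopyClassBins, PortraitMatrix


def plot_copy_class_histogram(bins: CopyClassBins, ax=None):
    """Bar histogram of copy-class counts, below-range bin included."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    labels = [f"(0,{fmt_threshold(bins.intervals[0][0])}]"] + [
        f"({fmt_threshold(lo)},{fmt_threshold(hi)}]" for lo, hi in bins.intervals
    ]
    ax.bar(range(len(labels)), [bins.below_range_count, *bins.counts], color="#4878a8")
    ax.set_xticks(range(len(labels)), labels, rotation=45, ha="right")
    ax.set_xlabel("RPKM interval")
    ax.set_ylabel("genes")
    ax.set_title(bins.layer_label)
    return ax


def plot_portrait(pm: PortraitMatrix, ax=None):
    """Horizontal bars of per-layer genome coverage percentages."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    j = pm.to_jsonable()
    layers = list(j["layer_coverage_percent"])
    pct = [j["layer_coverage_percent"][k] for k in layers]
    ax.barh(range(len(layers)), pct, color=["#4878a8", "#6aa84f", "#b45f06"])
    ax.set_yticks(range(len(layers)), [f"{k} ({pm.layer_labels[k]})" for k in layers])
    ax.set_xlabel("% of protein-coding universe detected")
    ax.set_xlim(0, 100)
    return ax
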