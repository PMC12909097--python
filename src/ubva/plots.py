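"""Figure families: severity distributions, scree, Manhattan, VIF scatter."""

from __future__ import annotations

from dataclasses import dataclass, field

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["PlotSpec", "render", "severity_distribution", "eigenvalue_scree",
           "manhattan", "vif_scatter"]

_KINDS = {"severity_distribution", "eigenvalue_scree", "manhattan",
          "vif_scatter"}

#: conventional annotation thresholds
VIF_THRESHOLD = 5.0
CONDITION_NUMBER_THRESHOLD = 10.0
SRS_CUTOFF = 0.3


@dataclass
class PlotSpec:
    kind: str
    data: object                      # DataFrame or dict of arrays
    out: str
    annotations: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValueError(f"unknown plot kind {self.kind!r}")
        if not str(self.out).endswith((".png", ".pdf", ".svg")):
            raise ValueError("output format must be png, pdf or svg")


def _require(data, cols):
    missing = [c for c in cols if c not in data]
    if missing:
        raise ValueError("missing column(s): " + ", ".join(missing))


def severity_distribution(data, out):
    """Three panels: sample eigenvalues, scaled left and right severities."""
    _require(data, ["eigenvalues", "sL", "sR"])
    fig, axes = plt.subplots(1, 3, figsize=(11, 3.2))
    for ax, key, label in zip(axes, ["eigenvalues", "sL", "sR"],
                              ["sample eigenvalues", "sL", "sR"]):
        ax.hist(np.asarray(data[key]), bins=40, color="#4878b0")
        ax.set_xlabel(label)
    axes[0].set_ylabel("count")
    fig.tight_layout()
    fig.savefig(out)
    plt.close(fig)


def eigenvalue_scree(data, out):
    _require(data, ["eigenvalues"])
    ev = np.sort(np.asarray(data["eigenvalues"]))[::-1]
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(np.arange(1, ev.size + 1), ev, ".-")
    ax.axhline(CONDITION_NUMBER_THRESHOLD, ls="--", color="grey",
               label="condition-number reference 10")
    ax.set_xlabel("component")
    ax.set_ylabel("sample eigenvalue")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(out)
    plt.close(fig)


def manhattan(data, out):
    """sR along the genome, chromosomes in order with alternating shading."""
    df = pd.DataFrame(data)
    _require(df, ["chrom", "pos", "sR"])
    fig, ax = plt.subplots(figsize=(9, 3.2))
    offset, ticks, labels = 0.0, [], []
    for i, (chrom, grp) in enumerate(df.groupby("chrom", sort=False)):
        x = offset + (grp["pos"] - grp["pos"].min())
        ax.scatter(x, grp["sR"], s=6,
                   color="#33548e" if i % 2 == 0 else "#8aa2c8")
        if i % 2 == 1:
            ax.axvspan(offset, x.max(), color="0.93", zorder=0)
        ticks.append(x.mean())
        labels.append(str(chrom))
        offset = x.max() + max(1.0, 0.01 * (x.max() - offset))
    ax.set_xticks(ticks, labels)
    ax.set_xlabel("chromosome")
    ax.set_ylabel("sR")
    fig.tight_layout()
    fig.savefig(out)
    plt.close(fig)


def vif_scatter(data, out):
    """VIF against sR with the conventional detection threshold at 5."""
    df = pd.DataFrame(data)
    _require(df, ["sR", "vif"])
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.scatter(df["sR"], df["vif"], s=10, color="#4878b0")
    ax.axhline(VIF_THRESHOLD, ls="--", color="firebrick",
               label="VIF threshold 5")
    ax.set_xlabel("sR")
    ax.set_ylabel("VIF")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(out)
    plt.close(fig)


_RENDERERS = {"severity_distribution": severity_distribution,
              "eigenvalue_scree": eigenvalue_scree,
              "manhattan": manhattan,
              "vif_scatter": vif_scatter}


def render(spec: PlotSpec) -> str:
    """Render a PlotSpec to its output path and return the path."""
    _RENDERERS[spec.kind](spec.data, spec.out)
    return str(spec.out)
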