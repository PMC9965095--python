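"""Summary figure: sensitivity and specificity per component, per sex."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .config import COMPONENTS
from .published import COMPONENT_NAMES


def sens_spec_figure(table: pd.DataFrame, path: str) -> None:
    """Grouped bar chart of sensitivity/specificity of the single markers.

    ``table`` is the tidy accuracy table (raw proportions) produced by
    :func:`frailtyscreen.accuracy.metrics_table`.
    """
    singles = table[table["rule"] == "single"]
    sexes = [s for s in ("male", "female") if (singles["sex"] == s).any()]
    fig, axes = plt.subplots(1, len(sexes), figsize=(5.2 * len(sexes), 3.6), squeeze=False)
    x = np.arange(len(COMPONENTS))
    for ax, sex in zip(axes[0], sexes):
        sub = singles[singles["sex"] == sex].set_index("marker")
        sens = [100 * sub.loc[c, "sensitivity"] for c in COMPONENTS]
        spec = [100 * sub.loc[c, "specificity"] for c in COMPONENTS]
        ax.bar(x - 0.18, sens, width=0.36, label="sensitivity", color="#33618d")
        ax.bar(x + 0.18, spec, width=0.36, label="specificity", color="#c98a3d")
        ax.set_xticks(x)
        ax.set_xticklabels(
            [COMPONENT_NAMES[c].replace("_", "\n") for c in COMPONENTS], fontsize=8
        )
        ax.set_ylim(0, 105)
        ax.set_ylabel("percent")
        ax.set_title(sex)
        ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
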