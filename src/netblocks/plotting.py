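"""Optional matplotlib curves of the evaluation criteria vs sample size."""

from __future__ import annotations

from .evaluation import EvalReport


def _curves(table: dict, variant: str):
    by_method: dict[str, dict[int, list[float]]] = {}
    for (method, size, var), value in table.items():
        if var != variant:
            continue
        by_method.setdefault(method, {}).setdefault(size, []).append(value)
    return {
        m: sorted((s, sum(v) / len(v)) for s, v in sizes.items())
        for m, sizes in by_method.items()
    }


def plot_criteria(report: EvalReport, variant: str = "JOINT_RATIO", out_path=None):
    """Two panels: mean motif MSE and mean R^2 against sample size, one
    line per sampling method.  Returns the matplotlib figure."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, (ax_mse, ax_r2) = plt.subplots(1, 2, figsize=(10, 4), sharex=True)
    for ax, table, label in ((ax_mse, report.mse_table, "mean motif MSE"),
                             (ax_r2, report.r2_table, "mean $R^2$")):
        for method, points in sorted(_curves(table, variant).items()):
            xs, ys = zip(*points)
            ax.plot(xs, ys, marker="o", label=method)
        ax.set_xlabel("sample size (nodes)")
        ax.set_ylabel(label)
    ax_mse.legend(fontsize=8)
    fig.suptitle(f"criteria vs sample size ({variant})")
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=150)
    return fig
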