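"""Figure-style plots for a run directory: trajectory fan, distance-to-pylorus
traces, ensemble stress envelopes, transpyloric flux, histograms, contact
force spikes."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from gastrosim import diagnostics

__all__ = ["plot_run"]


def plot_run(run_dir, out_dir) -> list[Path]:
    run_dir = Path(run_dir)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    flux = pd.read_csv(run_dir / "flux.csv")

    fig, ax = plt.subplots(figsize=(7, 3))
    ax.plot(flux["t"], flux["q"] * 4.0 * 60 / 1000, lw=0.6)
    ax.set_xlabel("t (s)")
    ax.set_ylabel("transpyloric flow (ml/min)")
    ax.axhline(0, color="k", lw=0.5)
    fig.tight_layout()
    p = out_dir / "flux.png"
    fig.savefig(p, dpi=150)
    plt.close(fig)
    paths.append(p)

    pfile = run_dir / "particles.csv"
    if pfile.exists():
        df = pd.read_csv(pfile)

        fig, ax = plt.subplots(figsize=(5, 6))
        for pid, sub in df.groupby("particle"):
            ax.plot(sub["x"], sub["y"], lw=0.7)
        ax.set_aspect("equal")
        ax.set_xlabel("x (mm)")
        ax.set_ylabel("y (mm)")
        ax.set_title("particle paths")
        fig.tight_layout()
        p = out_dir / "trajectories.png"
        fig.savefig(p, dpi=150)
        plt.close(fig)
        paths.append(p)

        fig, ax = plt.subplots(figsize=(7, 3.5))
        for pid, sub in df.groupby("particle"):
            ax.plot(sub["t"], sub["s"], lw=0.7)
        ax.set_xlabel("t (s)")
        ax.set_ylabel("distance to pylorus s (mm)")
        fig.tight_layout()
        p = out_dir / "distance_to_pylorus.png"
        fig.savefig(p, dpi=150)
        plt.close(fig)
        paths.append(p)

        env = diagnostics.ensemble_series(df)
        fig, axes = plt.subplots(2, 1, figsize=(7, 5), sharex=True)
        axes[0].fill_between(env["t"], env["tau_min"] * 1e3, env["tau_max"] * 1e3, alpha=0.3)
        axes[0].plot(env["t"], env["tau_mean"] * 1e3, lw=0.8)
        axes[0].set_ylabel("tau (mPa)")
        axes[1].fill_between(env["t"], env["p_min"], env["p_max"], alpha=0.3)
        axes[1].plot(env["t"], env["p_mean"], lw=0.8)
        axes[1].set_ylabel("p - p_duo (Pa)")
        axes[1].set_xlabel("t (s)")
        fig.tight_layout()
        p = out_dir / "stress_envelopes.png"
        fig.savefig(p, dpi=150)
        plt.close(fig)
        paths.append(p)

        post = df[df["t"] >= diagnostics.ANALYSIS_START]
        if not post.empty:
            fig, axes = plt.subplots(1, 2, figsize=(8, 3))
            axes[0].hist(post["p_bar"], bins=30)
            axes[0].set_xlabel("p - p_duo (Pa)")
            axes[1].hist(post["tau_bar"] * 1e3, bins=30)
            axes[1].set_xlabel("tau (mPa)")
            fig.tight_layout()
            p = out_dir / "histograms.png"
            fig.savefig(p, dpi=150)
            plt.close(fig)
            paths.append(p)

    cfile = run_dir / "contacts.csv"
    if cfile.exists():
        con = pd.read_csv(cfile)
        if not con.empty:
            fig, ax = plt.subplots(figsize=(7, 3))
            ax.vlines(con["t"], 0, con["f_max"], lw=0.6)
            ax.set_xlabel("t (s)")
            ax.set_ylabel("|F_c| (uN/mm)")
            fig.tight_layout()
            p = out_dir / "contact_forces.png"
            fig.savefig(p, dpi=150)
            plt.close(fig)
            paths.append(p)
    return paths
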