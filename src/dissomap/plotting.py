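"""Plot helpers: concentration-map heatmaps and profile overlays."""

from __future__ import annotations



from .metrics import DissolutionProfile
from .unmix import ConcentrationMap


def plot_concentration_map(cmap: ConcentrationMap, ax=None, **imshow_kwargs):
    """Heatmap of one HPMC concentration map (w/w %)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    extent_r = cmap.shape[0] * cmap.pixel_pitch_um
    extent_c = cmap.shape[1] * cmap.pixel_pitch_um
    im = ax.imshow(
        cmap.values,
        origin="lower",
        extent=(0, extent_c, 0, extent_r),
        cmap=imshow_kwargs.pop("cmap", "viridis"),
        **imshow_kwargs,
    )
    ax.set_xlabel("µm")
    ax.set_ylabel("µm")
    ax.set_title(f"{cmap.component} concentration (w/w %)")
    ax.figure.colorbar(im, ax=ax, label="w/w %")
    return ax


def plot_profiles(measured: DissolutionProfile, predicted: DissolutionProfile, ax=None):
    """Overlay a measured and a predicted dissolution profile."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(measured.times, measured.released, "o-", label="measured", ms=3)
    ax.plot(predicted.times, predicted.released, "s--", label="predicted", ms=3)
    ax.set_xlabel("time (min)")
    ax.set_ylabel("drug released (%)")
    ax.set_ylim(0, 110)
    ax.legend()
    return ax
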