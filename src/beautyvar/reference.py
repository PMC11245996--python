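"""Published summary statistics of the two reference beauty quartets.

Per-image beauty mean, beauty SD, and typicality for the Disputed-Beauty
Quartet (contested images: ratings spread over the whole scale) and the
Undisputed-Beauty Quartet (consensus images: everyone rates them about
the same).  Both quartets sit in the 3.5-4.0 mean-beauty window with
typicality >= 3; they differ only in spread.  These printed values are
inputs to the variance-contrast sanity checks (25 raters per arm).
"""

from __future__ import annotations

from .data import ImageSummary

N_RATERS_PER_ARM = 25

DISPUTED_QUARTET = (
    ImageSummary("bull_terrier", beauty_mean=3.5, beauty_sd=2.1,
                 typicality_mean=4.8, n_raters=N_RATERS_PER_ARM),
    ImageSummary("tacos", beauty_mean=3.9, beauty_sd=2.1,
                 typicality_mean=5.5, n_raters=N_RATERS_PER_ARM),
    ImageSummary("abstract_art", beauty_mean=3.5, beauty_sd=2.2,
                 typicality_mean=3.0, n_raters=N_RATERS_PER_ARM),
    ImageSummary("coral_reef", beauty_mean=3.6, beauty_sd=2.0,
                 typicality_mean=3.8, n_raters=N_RATERS_PER_ARM),
)

UNDISPUTED_QUARTET = (
    ImageSummary("bookshop", beauty_mean=3.8, beauty_sd=1.3,
                 typicality_mean=3.8, n_raters=N_RATERS_PER_ARM),
    ImageSummary("reeds", beauty_mean=4.0, beauty_sd=1.5,
                 typicality_mean=4.3, n_raters=N_RATERS_PER_ARM),
    ImageSummary("farm", beauty_mean=3.7, beauty_sd=1.4,
                 typicality_mean=4.5, n_raters=N_RATERS_PER_ARM),
    ImageSummary("house", beauty_mean=3.6, beauty_sd=1.6,
                 typicality_mean=5.8, n_raters=N_RATERS_PER_ARM),
)


def disputed_sds() -> list[float]:
    return [s.beauty_sd for s in DISPUTED_QUARTET]


def undisputed_sds() -> list[float]:
    return [s.beauty_sd for s in UNDISPUTED_QUARTET]


def disputed_means() -> list[float]:
    return [s.beauty_mean for s in DISPUTED_QUARTET]


def undisputed_means() -> list[float]:
    return [s.beauty_mean for s in UNDISPUTED_QUARTET]
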