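"""Published reference values used as worked-example inputs.

These constants transcribe the summary statistics of a published
three-classifier comparison on four public dermoscopy archives (PH2,
ISBI-2016, ISIC-2017, HAM10000): one-way ANOVA sums of squares with the
F statistic each table prints, and the feature-fusion dimension table with
its reduction percentages.  They are inputs for recomputation — the package
re-derives every F statistic and reduction percentage from the raw sums of
squares and widths.

Two reduction rows are arithmetically inconsistent with their own printed
widths (``ph2 / fi+fn``: 1980/2592 rounds to 76, printed 77; ``isic2017 /
fd+fi+fn``: 3587/4512 rounds to 79, printed 70).  ``reduction_printed`` is
``None`` for those rows and the recomputed value is the reference.
"""

from __future__ import annotations

# per-extractor feature widths: DenseNet-201, Inception-ResNet v2,
# NASNet-Mobile
BLOCK_WIDTHS: dict[str, int] = {"fd": 1920, "fi": 1536, "fn": 1056}

# one-way ANOVA summaries (3 classifiers x 5 accuracy samples each)
ANOVA_SUMMARIES: dict[str, dict[str, float | int]] = {
    "ph2": {
        "ss_between": 9.6274, "ss_within": 2.5001,
        "df_between": 2, "df_within": 12, "f_printed": 23.1046,
    },
    "isbi2016": {
        "ss_between": 15.6484, "ss_within": 1.6800,
        "df_between": 2, "df_within": 12, "f_printed": 55.8885,
    },
    "isic2017": {
        "ss_between": 39.5290, "ss_within": 5.6196,
        "df_between": 2, "df_within": 12, "f_printed": 42.2048,
    },
    "ham10000": {
        "ss_between": 14.3080, "ss_within": 4.8566,
        "df_between": 2, "df_within": 12, "f_printed": 17.6766,
    },
}

F_CRITICAL_2_12_005 = 3.89

# (dataset, blocks, input width, selected width, printed reduction %)
FUSION_REDUCTIONS: list[tuple[str, tuple[str, ...], int, int, int | None]] = [
    ("ph2", ("fd", "fi"), 3456, 592, 83),
    ("ph2", ("fi", "fn"), 2592, 612, None),        # printed 77; arithmetic 76
    ("ph2", ("fd", "fn"), 2976, 571, 81),
    ("ph2", ("fd", "fi", "fn"), 4512, 970, 79),
    ("isbi2016", ("fd", "fi"), 3456, 795, 77),
    ("isbi2016", ("fi", "fn"), 2592, 804, 69),
    ("isbi2016", ("fd", "fn"), 2976, 803, 73),
    ("isbi2016", ("fd", "fi", "fn"), 4512, 948, 79),
    ("isic2017", ("fd", "fi"), 3456, 1106, 68),
    ("isic2017", ("fi", "fn"), 2592, 1011, 61),
    ("isic2017", ("fd", "fn"), 2976, 1071, 64),
    ("isic2017", ("fd", "fi", "fn"), 4512, 925, None),  # printed 70; arithmetic 79
    ("ham10000", ("fd", "fi"), 3456, 1210, 65),
    ("ham10000", ("fi", "fn"), 2592, 1063, 59),
    ("ham10000", ("fd", "fn"), 2976, 1161, 61),
    ("ham10000", ("fd", "fi", "fn"), 4512, 1489, 67),
]
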