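"""Blind randomized presentation order for ROI scoring.

The scorer sees only opaque blinded IDs and image references, in a seeded
random order; the sealed key maps them back to animal and group afterwards.
"""

from ps6quant import CohortSpec, StainFieldSpec, blind_order, generate_cohort

spec = CohortSpec(regions=("NDI", "TOp"), n_per_group=2, rois_per_region=1,
                  base_field=StainFieldSpec(image_shape=(96, 96)), seed=3)
cohort = generate_cohort(spec)

presentation, key = blind_order(cohort.metadata(), seed=42)
print("presented to the scorer (no group/animal labels):")
print(presentation.head(5).to_string(index=False))
print("\nsealed unblinding key (kept apart until scoring is done):")
print(key.head(5).to_string(index=False))
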