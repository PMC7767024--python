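# Default Van Krevelen class boundary table.
#
# Each class is a rectangle in O:C (x) by H:C (y) space. Classes are
# evaluated in the order listed; the FIRST rectangle containing a point
# wins, which resolves any overlap deterministically. A point outside
# every rectangle is labelled "other".
#
# Bounds are inclusive unless the matching *_inclusive flag is false.
# These defaults follow the rectangle conventions in common use for
# FTICR-MS organic-matter panels; substitute your preferred boundary set
# by pointing the pipeline at another file with the same schema.
classes:
  - name: lipid-like
    oc_min: 0.0
    oc_max: 0.3
    oc_max_inclusive: false
    hc_min: 1.5
    hc_max: 2.5
  - name: protein-like
    oc_min: 0.3
    oc_max: 0.55
    oc_max_inclusive: false
    hc_min: 1.5
    hc_max: 2.3
  - name: amino-sugar-like
    oc_min: 0.55
    oc_max: 0.7
    oc_max_inclusive: false
    hc_min: 1.5
    hc_max: 2.2
  - name: carbohydrate-like
    oc_min: 0.7
    oc_max: 1.5
    hc_min: 1.5
    hc_max: 2.5
  - name: unsaturated-hydrocarbon-like
    oc_min: 0.0
    oc_max: 0.125
    oc_max_inclusive: false
    hc_min: 0.8
    hc_max: 1.5
    hc_max_inclusive: false
  - name: lignin-like
    oc_min: 0.125
    oc_max: 0.65
    oc_max_inclusive: false
    hc_min: 0.8
    hc_max: 1.5
    hc_max_inclusive: false
  - name: tannin-like
    oc_min: 0.65
    oc_max: 1.1
    hc_min: 0.8
    hc_max: 1.5
    hc_max_inclusive: false
  - name: condensed-hydrocarbon-like
    oc_min: 0.0
    oc_max: 0.95
    hc_min: 0.2
    hc_max: 0.8
    hc_max_inclusive: false
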