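# Packaged quantitative scoring criteria.
#
# Each rule maps a measured quantity (here a ratio) onto the 1-5 metric scale.
# `breakpoints` are the four interval edges separating the five levels in
# ascending order; `boundary_side[i]` says whether a value exactly equal to
# breakpoints[i] belongs to the interval below ("lower") or above ("upper").
# For the crew-earnings rule the published criteria make the middle band
# closed ("Within 10% of the regional average") and the top band open ("More
# than 50% above"), which fixes the 1.1 and 1.5 edges; the 0.5 and 0.9 edges
# are assigned to the band closer to the scale midpoint.
crew_earnings:
  metric_id: crew_earnings
  units: "ratio of annual crew earnings from fishing to regional average earnings"
  domain_min: 0.0
  breakpoints: [0.5, 0.9, 1.1, 1.5]
  boundary_side: [upper, upper, lower, lower]
  direction: benefit
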