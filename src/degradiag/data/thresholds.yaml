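# Grade-class thresholds for the five cultivated-land evaluation indicators,
# per land-use class (paddy / dryland).  Four classes per cell, listed
# best-first; each class is a union of closed [low, high] intervals.
# Classes are scanned best -> worst and the first match wins, so a value on a
# shared boundary resolves to the better grade.  `.inf` / `-.inf` mark
# unbounded sides.  BD and SLOPE use one shared row for both land uses.
# Units: SOM, TN g/kg; pH unitless; BD g/cm^3; SLOPE degrees.
som:
  dryland:
    - [[20.0, .inf]]
    - [[15.0, 20.0]]
    - [[10.0, 15.0]]
    - [[0.0, 10.0]]
  paddy:
    - [[30.0, .inf]]
    - [[25.0, 30.0]]
    - [[15.0, 25.0]]
    - [[0.0, 15.0]]
tn:
  dryland:
    - [[20.0, .inf]]
    - [[15.0, 20.0]]
    - [[10.0, 15.0]]
    - [[0.0, 10.0]]
  paddy:
    - [[30.0, .inf]]
    - [[25.0, 30.0]]
    - [[15.0, 25.0]]
    - [[0.0, 15.0]]
ph:
  dryland:
    - [[6.0, 14.0]]
    - [[5.5, 6.0]]
    - [[4.5, 5.5]]
    - [[0.0, 4.5]]
  paddy:
    - [[5.5, 14.0]]
    - [[5.0, 5.5]]
    - [[4.5, 5.0]]
    - [[0.0, 4.5]]
bd:
  dryland: &bd_classes
    - [[1.00, 1.25]]
    - [[1.25, 1.35], [0.90, 1.00]]
    - [[1.35, 1.45]]
    - [[1.45, .inf], [0.0, 0.90]]
  paddy: *bd_classes
slope:
  dryland: &slope_classes
    - [[0.0, 5.0]]
    - [[5.0, 8.0]]
    - [[8.0, 18.0]]
    - [[18.0, .inf]]
  paddy: *slope_classes
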