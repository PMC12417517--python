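"""Published reference values from the urban AED/OHCA study this model
emulates, used as fixtures: a benefit profile over the printed radius grid,
the golden-window walking column, and the location-type inventory."""

# radius (m) -> (mean accessible devices, percent of cases covered)
REFERENCE_PROFILE = {
    100: (0.11, 7.93),
    150: (0.24, 16.87),
    200: (0.43, 26.67),
    250: (0.67, 36.74),
    300: (1.00, 47.63),
    350: (1.38, 59.26),
    400: (1.82, 68.00),
}

# 3-minute walking-route column of the same table
REFERENCE_GOLDEN_WINDOW = {"avg": 1.19, "pct": 53.04}

# 100 m walking-route column
REFERENCE_100M_WALK = {"avg": 0.07, "pct": 7.33}

# location-type counts: type -> (event count, device count)
REFERENCE_TYPE_COUNTS = {
    "community": (1058, 352),
    "school": (26, 204),
    "medical": (49, 349),
    "commercial": (93, 28),
    "administration": (27, 211),
    "highway": (26, 0),
    "enterprise": (22, 16),
    "station": (29, 63),
    "tourist": (20, 15),
}

# printed percentages alongside the counts above
REFERENCE_TYPE_PCT = {
    "community": (78.4, 28.4),
    "school": (1.9, 16.5),
    "medical": (3.6, 28.2),
    "commercial": (6.9, 2.3),
    "administration": (2.0, 17.0),
    "highway": (1.9, 0.0),
    "enterprise": (1.6, 1.3),
    "station": (2.2, 5.1),
    "tourist": (1.5, 1.2),
}

# inter-device nearest-neighbour spacing summary (m)
REFERENCE_DEVICE_SPACING = {
    "min": 0.00, "q1": 0.00, "median": 162.27, "q3": 546.85,
    "max": 6183.95, "mean": 497.96, "sd": 838.17,
}

# event-to-nearest-device distance summaries (m)
REFERENCE_EVENT_DISTANCE = {
    "straight": {"min": 0.00, "q1": 190.75, "median": 307.12, "q3": 434.31,
                 "max": 3993.28, "mean": 378.94, "sd": 351.74},
    "route": {"min": 0.00, "q1": 195.06, "median": 327.15, "q3": 450.00,
              "max": 5343.29, "mean": 407.09, "sd": 442.30},
}
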