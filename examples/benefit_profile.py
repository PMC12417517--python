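"""Ring-buffer benefit profile and golden-window coverage.

For radii from 100 m to 450 m in 20 m steps, computes the mean number of
devices within radius of each arrest case (avg) and the percentage of cases
with at least one device in range (pct), then evaluates coverage at the
3-minute walking-route budget (270 m at 1.5 m/s) — half the 6-minute golden
window before irreversible brain injury begins without CPR.
"""

from aed_golden import (CityConfig, WalkWindow, benefit_profile, generate_city,
                        golden_window_coverage)

city = generate_city(CityConfig(seed=7))

profile = benefit_profile(city.event_xy, city.device_xy)
print("radius (m)   avg devices   % covered")
for r, a, p in zip(profile.radii, profile.avg_devices, profile.pct_covered):
    print(f"{r:8.0f}     {a:8.2f}     {p:8.2f}")

window = WalkWindow()  # 180 s at 1.5 m/s -> 270 m route budget
pct, avg, counts = golden_window_coverage(city.event_xy, city.device_xy,
                                          city.graph, window)
print(f"\n3-min walking window ({window.budget:.0f} m route budget): "
      f"{pct:.2f}% of cases reach a device, {avg:.2f} devices per case on average")
print("Both rows rise with radius; avg >= pct/100 always, since every covered "
      "case contributes at least one device.")
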