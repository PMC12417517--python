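# End-to-end pipeline configuration for a synthetic city.
# Remove the `synthetic` block and supply events/devices/network/region
# paths instead to run on real files.
seed: 7
output_dir: out
synthetic:
  n_events: 1350
  n_devices: 1238
  grid_spacing: 50.0        # m between walking-network nodes
  device_cluster_count: 60
  device_cluster_sd: 60.0   # m
  duplicate_device_frac: 0.15
radii: {start: 100, stop: 450, step: 20}
walk_window: {duration: 180, speed: 1.5}   # 3 min at 1.5 m/s -> 270 m budget
target: {avg: 1.0, pct: 40.0}
placement: {n_points: 100, band_low: 250.0, band_high: 300.0, coverage_radius: 270.0}
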