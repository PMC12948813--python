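"""Derive modelled ERG waveforms at arbitrary in-range flash strengths.

Because f(t, FS) is continuous in FS, waveforms can be read off at flash
strengths that were never presented, as long as they lie inside the fitted
range.  The default list spans 15-400 Td.s.
"""

import ergsurf as es

data, _ = es.generate_dataset(es.DesignTable.balanced(12, groups=("control",)),
                              es.SyntheticParams(n_samples=50), seed=1)
model = es.fit_gam(data, es.ModelSpec(k_t=14, k_fs=6), group="control")

waves = es.derived_waveforms(model, n_t=120)  # default nine flash strengths
for fs, grp in waves.groupby("flash_td_s"):
    trough = grp.loc[grp["estimate_uv"].idxmin()]
    peak = grp.loc[grp["estimate_uv"].idxmax()]
    print(f"FS {fs:5.0f} Td.s: trough {trough.estimate_uv:6.1f} uV @ {trough.time_ms:5.1f} ms, "
          f"peak {peak.estimate_uv:5.1f} uV @ {peak.time_ms:5.1f} ms")
# Trough deepens and peak grows with flash strength (saturating), the
# photopic-hill-like behavior built into the generator.
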