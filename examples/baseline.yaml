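# Baseline producing-cell aggregation model: full network (aggregates up to
# 200 Shh), default calibrated kinetics, 24-hour simulation with the
# dispersal-removal variant alongside.  All model/parameter keys omitted
# here take their package defaults.
max_size: 200
report_size: 40
t_end: 1440.0            # minutes
snapshot_times: [30.0, 60.0, 180.0, 360.0, 720.0, 1440.0]
scenarios: [no_dispersal]
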