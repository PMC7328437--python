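# Default intensity parameterisation, calibrated so that weekday activity
# participation rates and episode durations of simulated commuter and retired
# agents match UK time-use statistics.  Rates are per minute of simulated time.

[global]
sigma_rate = 0.2
window_offset_min = 75.0
daily_jitter_min = 10.0
walking_speed_mps = 1.4
step_minutes = 5.0
initial_radius_m = 500.0
max_doublings = 6

# ---------------------------------------------------------------- commuters

[commuter.at_home]
grow_rate = 0.0008
decay_rate = 0.004
amplitude = 1.0
baseline = 0.5
window_start = "20:30"
window_end = "08:45"
min_duration_min = 60.0
duration_sigma = 0.0

[commuter.work]
grow_rate = 0.0
decay_rate = 0.004
amplitude = 1.6
window_start = "08:15"
window_end = "16:45"
min_duration_min = 60.0
duration_sigma = 0.0

[commuter.shop_food]
grow_rate = 4.5e-5
decay_rate = 0.0119
amplitude = 0.55
window_start = "16:00"
window_end = "17:45"
min_duration_min = 30.0
duration_sigma = 0.8

[commuter.lunch_out]
grow_rate = 7.9e-6
decay_rate = 0.00833
amplitude = 1.35
window_start = "12:00"
window_end = "13:30"
min_duration_min = 30.0
duration_sigma = 0.8

[commuter.evening_social]
grow_rate = 8.9e-6
decay_rate = 0.00333
amplitude = 0.30
window_start = "19:00"
window_end = "22:00"
min_duration_min = 60.0
duration_sigma = 0.8

[commuter.sports]
grow_rate = 1.94e-5
decay_rate = 0.00333
amplitude = 0.30
window_start = "17:30"
window_end = "21:00"
min_duration_min = 60.0
duration_sigma = 0.8

# ------------------------------------------------------------ retired people

[retired.at_home]
grow_rate = 0.0008
decay_rate = 0.004
amplitude = 1.0
baseline = 0.5
window_start = "21:00"
window_end = "09:00"
min_duration_min = 60.0
duration_sigma = 0.0

[retired.shop_food]
grow_rate = 4.86e-5
decay_rate = 0.003
amplitude = 0.35
window_start = "09:00"
window_end = "16:00"
min_duration_min = 50.0
duration_sigma = 0.8

[retired.shop_leisure]
grow_rate = 2.15e-5
decay_rate = 0.00333
amplitude = 0.30
window_start = "10:00"
window_end = "16:30"
min_duration_min = 60.0
duration_sigma = 0.8

[retired.lunch_out]
grow_rate = 1.0e-5
decay_rate = 0.005
amplitude = 0.30
window_start = "12:00"
window_end = "13:30"
min_duration_min = 40.0
duration_sigma = 0.8

[retired.evening_social]
grow_rate = 9.9e-6
decay_rate = 0.00333
amplitude = 0.30
window_start = "18:30"
window_end = "21:30"
min_duration_min = 60.0
duration_sigma = 0.8

[retired.sports]
grow_rate = 2.33e-5
decay_rate = 0.00333
amplitude = 0.30
window_start = "09:30"
window_end = "12:30"
min_duration_min = 60.0
duration_sigma = 0.8
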