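# Constant weather context used by the canonical verification fixtures,
# plus the thresholds the weather-classification rule compares against.

[constant]
city = "Grimstad"
country = "Norway"
weather_code = 800          # clear sky in the OpenWeather code scheme
status = "Clear"
description = "clear sky"
temperature_c = 18.0
real_feel_c = 17.0
pressure_hpa = 1013.0
humidity_pct = 60.0
visibility_m = 10000.0
wind_speed_ms = 4.0
timestamp = "2022-06-01T08:00:00"

[thresholds]
# Outdoor activity is advised when the temperature lies in [t_min_c, t_max_c]
# (inclusive), wind speed is at most wind_max_ms, and the weather code is not
# in severe_codes (thunderstorm 2xx, heavy rain/snow groups).
t_min_c = 0.0
t_max_c = 30.0
wind_max_ms = 10.0
severe_codes = [200, 201, 202, 210, 211, 212, 221, 230, 231, 232, 502, 503, 504, 511, 522, 602, 622, 771, 781]
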