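PREFIX onto: <https://example.org/ecoach/onto#>
SELECT ?context ?city ?country ?code ?temperature ?humidity ?wind
WHERE {
  ?context onto:hasContextValue ?value .
  ?value onto:hasCity ?city .
  ?value onto:hasCountry ?country .
  ?value onto:hasWeatherCode ?code .
  ?value onto:hasTemperature ?temperature .
  ?value onto:hasHumidity ?humidity .
  ?value onto:hasWindSpeed ?wind .
}
ORDER BY ?context
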