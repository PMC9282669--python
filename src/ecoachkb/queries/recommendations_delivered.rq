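PREFIX onto: <https://example.org/ecoach/onto#>
SELECT ?participant ?code ?datetime
WHERE {
  ?participant onto:hasReceivedRecommendation ?rec .
  ?rec onto:hasMessageCode ?code .
  ?rec onto:hasRecommendationDateTime ?datetime .
}
ORDER BY ?participant ?code
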