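# Default policy-instrument taxonomy: 3 categories, 16 sub-tools.
categories:
  - id: supply
    label: Supply-based
    sub_tools:
      - Infrastructure construction
      - Technology support
      - Talent development
      - Information support
      - Financial support
  - id: environment
    label: Environment-based
    sub_tools:
      - Tax incentives
      - Strategic measures
      - Regulatory control
      - Institution building
      - Target planning
      - Policy publicity
  - id: demand
    label: Demand-based
    sub_tools:
      - Government purchasing
      - Policy subsidies
      - Service outsourcing
      - Market cultivation
      - Demonstration pilots
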