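# Default evaluation rubric: 10 first-level variables, 46 binary second-level
# criteria. X10 has no criteria and is scored directly (0/1).
version: ltci-pilot-default
variables:
  - id: X1
    label: Policy nature
    criteria:
      - {id: X1-1, label: Prediction, criterion: "Reflects predictions and forward-looking elements (coverage expansion, industry development, talent structure); yes 1, no 0"}
      - {id: X1-2, label: Recommendation, criterion: "Provides comments or recommendations on development; yes 1, no 0"}
      - {id: X1-3, label: Feedback, criterion: "Has a corresponding feedback channel for problems; yes 1, no 0"}
      - {id: X1-4, label: Supervision, criterion: "Has a corresponding supervision method; yes 1, no 0"}
      - {id: X1-5, label: Description, criterion: "Details scope of participation, financing, disability assessment, treatment guarantee, fund/service management; yes 1, no 0"}
      - {id: X1-6, label: Orientation, criterion: "Embodies people-centered service values; yes 1, no 0"}
  - id: X2
    label: Policy timeliness
    criteria:
      - {id: X2-1, label: Long-term, criterion: "Impact effectiveness 5 years and above; yes 1, no 0"}
      - {id: X2-2, label: Medium-term, criterion: "Impact effectiveness 3-5 years; yes 1, no 0"}
      - {id: X2-3, label: Short-term, criterion: "Impact effectiveness 1-3 years; yes 1, no 0"}
      - {id: X2-4, label: Within the year, criterion: "Impact effectiveness less than 1 year; yes 1, no 0"}
  - id: X3
    label: Policy level
    criteria:
      - {id: X3-1, label: Administrative/local legislation, criterion: "Administrative or local legislation; yes 1, no 0"}
      - {id: X3-2, label: Departmental/local regulation, criterion: "Departmental or local government regulation; yes 1, no 0"}
      - {id: X3-3, label: Normative document, criterion: "Normative document; yes 1, no 0"}
      - {id: X3-4, label: Industry regulation, criterion: "Industry regulation; yes 1, no 0"}
  - id: X4
    label: Policy subject
    criteria:
      - {id: X4-1, label: The government, criterion: "Involves the government; yes 1, no 0"}
      - {id: X4-2, label: Insurance companies, criterion: "Involves insurance companies; yes 1, no 0"}
      - {id: X4-3, label: Professional care organizations, criterion: "Involves professional care organizations; yes 1, no 0"}
      - {id: X4-4, label: Social organizations, criterion: "Involves social organizations; yes 1, no 0"}
      - {id: X4-5, label: Third-party assessment organizations, criterion: "Involves third-party assessment organizations; yes 1, no 0"}
      - {id: X4-6, label: The public, criterion: "Involves the public (urban employees, urban and rural residents); yes 1, no 0"}
      - {id: X4-7, label: Beneficiaries, criterion: "Involves beneficiaries such as the disabled; yes 1, no 0"}
  - id: X5
    label: Policy objective
    criteria:
      - {id: X5-1, label: Care guarantee, criterion: "Provides care guarantee for the disabled; yes 1, no 0"}
      - {id: X5-2, label: Financial compensation, criterion: "Provides financial protection or compensation; yes 1, no 0"}
      - {id: X5-3, label: Pilot extension, criterion: "Involves pilot extension of the insurance; yes 1, no 0"}
  - id: X6
    label: Policy content
    criteria:
      - {id: X6-1, label: Disability assessment, criterion: "Involves disability assessment; yes 1, no 0"}
      - {id: X6-2, label: Funding, criterion: "Involves funding; yes 1, no 0"}
      - {id: X6-3, label: Service provision, criterion: "Involves service provision; yes 1, no 0"}
      - {id: X6-4, label: Treatment payment, criterion: "Involves treatment payment; yes 1, no 0"}
      - {id: X6-5, label: Standardized management, criterion: "Involves standardized management of funds, services, administration; yes 1, no 0"}
      - {id: X6-6, label: Organization and implementation, criterion: "Involves supporting measures and operational mechanisms; yes 1, no 0"}
  - id: X7
    label: Incentive and constraint
    criteria:
      - {id: X7-1, label: Financial inputs, criterion: "Includes financial inputs; yes 1, no 0"}
      - {id: X7-2, label: Tax incentives, criterion: "Includes tax incentives; yes 1, no 0"}
      - {id: X7-3, label: Financial support, criterion: "Includes financial support; yes 1, no 0"}
      - {id: X7-4, label: Talent training, criterion: "Includes talent training; yes 1, no 0"}
      - {id: X7-5, label: Government purchasing, criterion: "Includes government purchasing; yes 1, no 0"}
      - {id: X7-6, label: Information support, criterion: "Includes information support; yes 1, no 0"}
      - {id: X7-7, label: Institutional guarantee, criterion: "Includes institutional guarantees such as institutional mechanisms; yes 1, no 0"}
  - id: X8
    label: Policy function
    criteria:
      - {id: X8-1, label: Macro design, criterion: "Institutional design or overall planning from a macro perspective; yes 1, no 0"}
      - {id: X8-2, label: Supervisory constraints, criterion: "Involves supervision and constraints of implementation; yes 1, no 0"}
      - {id: X8-3, label: Normative guidance, criterion: "Normative guidance of institutional details; yes 1, no 0"}
      - {id: X8-4, label: Encouragement and motivation, criterion: "Contains measures of encouragement and motivation; yes 1, no 0"}
      - {id: X8-5, label: Service optimization, criterion: "Involves system improvement and service optimization; yes 1, no 0"}
  - id: X9
    label: Policy evaluation
    criteria:
      - {id: X9-1, label: Well founded, criterion: "Sufficient foundation (national laws, central government documents); yes 1, no 0"}
      - {id: X9-2, label: Clear objectives, criterion: "Has clear objectives; yes 1, no 0"}
      - {id: X9-3, label: Detailed planning, criterion: "Policy plan is detailed; yes 1, no 0"}
      - {id: X9-4, label: Scientific program, criterion: "Policy program is scientific and feasible; yes 1, no 0"}
  - id: X10
    label: Policy information disclosure
    criteria: []
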