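need_id,primary_need,secondary_need
Q1,Organizational management and mechanism,Performance-based compensation
Q2,Organizational management and mechanism,Business archive co-construction and sharing mechanism (emergency response plan and technical solution)
Q3,Organizational management and mechanism,Public health emergency rescue mechanism (emergency material reserve and cross-regional material mobilization)
Q4,Organizational management and mechanism,Collaborative release and interaction mechanism of social integrated media information
Q5,Handling of public health emergencies,"Cross-regional case monitoring, investigation, and tracking"
Q6,Handling of public health emergencies,Regional monitoring and early-warning information management system
Q7,Handling of public health emergencies,Coordinated transfer and diversion diagnosis and treatment of patients with infectious diseases within the region
Q8,Handling of public health emergencies,Joint risk assessment and emergency command
Q9,Public health governance,Community chronic disease prevention and services
Q10,Public health governance,Entity institutions for the collaborative governance of public health
Q11,Talent cultivation,Talent exchange and scientific research innovation cooperation
Q12,Talent cultivation,Regional co-construction and sharing between the university and the local area
Q13,Talent cultivation,Construction of a cross-regional expert database
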