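## General Information
1. Can you tell me your full name and what name you prefer to go by?
2. What is your date of birth and current age?
3. Where do you currently live, and who lives with you?
4. What do you do for work, and how long have you been in that role?
5. How would you describe your ethnicity or cultural background?
6. What is your current relationship status?
7. Do you have any children? If so, what are their names and ages?
8. Do you identify as having any disability or long-term condition that affects daily life?
9. What brings you in today — what is the main reason for this visit?

## Medical History
10. Have you ever been diagnosed with a psychiatric or mental health condition?
11. Are you currently taking any psychiatric medications? Please include the doses if you know them.
12. Have you taken psychiatric medications in the past that were stopped or changed?
13. Do you take any other prescription medications, supplements, or vitamins?
14. Do you have any allergies to medications, foods, or anything else?
15. Have you ever been hospitalized for a mental health concern?
16. Have you ever experienced thoughts of harming yourself or others? If so, when most recently?
17. Do you have any significant medical conditions, past injuries, or surgeries?
18. How would you describe your sleep lately, in terms of duration and quality?
19. How has your appetite or weight changed recently?
20. Do you use alcohol, tobacco, cannabis, or other recreational substances? How often?

## Family History
21. Are your parents living, and how would you describe your relationship with them?
22. Do you have siblings, and how do you get along with them?
23. Is there any history of mental illness in your family?
24. Is there any history of substance use problems in your family?
25. Are there significant medical conditions that run in your family?
26. Who in your family or social circle do you feel closest to?
27. Were there any major disruptions in your family while you were growing up?
28. Is there anything about your family situation now that causes you stress?

## Personal History
29. Where were you born, and where did you grow up?
30. How would you describe your childhood overall?
31. How far did you go in school, and how was that experience for you?
32. Can you walk me through your work history?
33. Have you had any past marriages or significant relationships?
34. Can you tell me a bit more about how those relationships ended?
35. How do you usually spend a typical day?
36. What do you do to relax or manage stress?
37. What are your main interests or hobbies?
38. How would you describe your current social life and friendships?
39. Have you experienced any traumatic or very distressing events?
40. Have you ever had legal problems or involvement with the courts?
41. How are things financially — are there any major stresses there?
42. What are your goals or hopes for the next few years?

## Additional Comments
43. Is there anything about your current situation we have not covered that you would like to mention?
44. Is there anything you are worried about regarding treatment or next steps?
45. What would you most like help with from our service?
46. Do you have any questions for me?
47. That is everything I needed to ask — is there anything else you would like to add before we finish?
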