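{
  "locales": {
    "en_CA": {
      "given_female": ["Emily", "Olivia", "Charlotte", "Sarah", "Hannah", "Grace", "Megan", "Claire", "Jessica", "Rachel", "Laura", "Erin"],
      "given_male": ["Liam", "Noah", "Ethan", "Jacob", "Owen", "Benjamin", "Lucas", "Nathan", "Ryan", "Connor", "Adam", "Scott"],
      "surnames": ["Smith", "Brown", "Tremblay", "Martin", "Wilson", "Campbell", "Anderson", "Taylor", "Johnston", "MacDonald", "Reid", "Stewart"]
    },
    "zh": {
      "given_female": ["Wei", "Xiu Ying", "Na", "Min", "Jing", "Li", "Yan", "Hui", "Fang", "Mei"],
      "given_male": ["Wei", "Jun", "Ming", "Hao", "Lei", "Qiang", "Tao", "Bin", "Feng", "Cheng"],
      "surnames": ["Wang", "Li", "Zhang", "Chen", "Liu", "Yang", "Huang", "Wu", "Zhou", "Lin"]
    },
    "hi_IN": {
      "given_female": ["Priya", "Ananya", "Aisha", "Kavya", "Neha", "Pooja", "Riya", "Shreya", "Divya", "Meera"],
      "given_male": ["Arjun", "Rohan", "Aditya", "Vikram", "Rahul", "Karan", "Sanjay", "Amit", "Nikhil", "Dev"],
      "surnames": ["Sharma", "Patel", "Singh", "Gill", "Kaur", "Mehta", "Reddy", "Gupta", "Joshi", "Malhotra"]
    },
    "fil_PH": {
      "given_female": ["Maria", "Angelica", "Jasmine", "Rosario", "Kristine", "Camille", "Liza", "Teresa"],
      "given_male": ["Jose", "Juan", "Miguel", "Paolo", "Rafael", "Andres", "Marco", "Dante"],
      "surnames": ["Santos", "Reyes", "Cruz", "Bautista", "Garcia", "Mendoza", "Flores", "Ramos"]
    },
    "fr_CA": {
      "given_female": ["Camille", "Sophie", "Juliette", "Amelie", "Chloe", "Genevieve", "Madeleine", "Elise"],
      "given_male": ["Olivier", "Mathieu", "Gabriel", "Antoine", "Philippe", "Etienne", "Marc", "Luc"],
      "surnames": ["Gagnon", "Roy", "Cote", "Bouchard", "Gauthier", "Morin", "Lavoie", "Fortin"]
    },
    "ko": {
      "given_female": ["Ji-woo", "Seo-yeon", "Min-ji", "Ha-eun", "Soo-jin", "Yuna", "Eun-ji", "Hye-jin"],
      "given_male": ["Min-jun", "Ji-ho", "Seo-jun", "Hyun-woo", "Dong-hyun", "Jae-won", "Sung-min", "Tae-yang"],
      "surnames": ["Kim", "Lee", "Park", "Choi", "Jung", "Kang", "Cho", "Yoon"]
    },
    "es": {
      "given_female": ["Sofia", "Valentina", "Camila", "Isabella", "Lucia", "Mariana", "Daniela", "Gabriela"],
      "given_male": ["Santiago", "Mateo", "Sebastian", "Diego", "Alejandro", "Andres", "Javier", "Carlos"],
      "surnames": ["Garcia", "Rodriguez", "Martinez", "Hernandez", "Lopez", "Gonzalez", "Perez", "Torres"]
    },
    "fa_IR": {
      "given_female": ["Sara", "Niloufar", "Maryam", "Leila", "Shirin", "Azadeh", "Parisa", "Yasaman"],
      "given_male": ["Amir", "Reza", "Arash", "Babak", "Kian", "Farhad", "Omid", "Navid"],
      "surnames": ["Ahmadi", "Hosseini", "Karimi", "Moradi", "Rahimi", "Jafari", "Sadeghi", "Tehrani"]
    }
  },
  "occupations": ["retail associate", "software developer", "registered nurse", "elementary school teacher", "warehouse worker", "barista", "accountant", "construction labourer", "graphic designer", "care aide", "delivery driver", "administrative assistant", "line cook", "electrician", "physiotherapy assistant", "customer support agent", "graduate student", "landscaper", "pharmacist", "currently unemployed"],
  "street_names": ["Maple Street", "Oak Avenue", "Fraser Street", "Main Street", "Cedar Crescent", "Willow Drive", "Granville Street", "Birch Lane", "Hastings Street", "Cambie Road", "Lonsdale Avenue", "Marine Drive"],
  "cities": ["Vancouver", "Burnaby", "Surrey", "Richmond", "North Vancouver", "Coquitlam", "New Westminster", "Langley"]
}
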